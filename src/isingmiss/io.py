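"""CSV I/O for response data and Ising matrices.

Responses: header row of item names, one row per respondent, values in
{0, 1} plus a configurable missing token (default "NA"; the survey-data
dialect "Unknown" and empty fields are also treated as missing).

Matrices: square CSV with a matching header; symmetry is validated on read
(tolerance 1e-8) and the matrix symmetrized by averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ising import IsingMatrix, ResponseData

DEFAULT_MISSING_TOKENS = ("NA", "Unknown", "")


def read_responses(path, missing_tokens=DEFAULT_MISSING_TOKENS) -> ResponseData:
    if isinstance(missing_tokens, str):
        missing_tokens = (missing_tokens,)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    raw = df.to_numpy()
    mask = ~np.isin(raw, list(missing_tokens))
    y = np.zeros(raw.shape, dtype=np.int8)
    vals = raw[mask]
    bad = ~np.isin(vals, ("0", "1"))
    if bad.any():
        raise ValueError(
            f"non-binary response values: {sorted(set(vals[bad]))[:5]} "
            f"(allowed: 0, 1 and missing tokens {missing_tokens})"
        )
    y[mask] = vals.astype(np.int8)
    return ResponseData(y, mask, items=tuple(df.columns))


def write_responses(data: ResponseData, path, missing_token: str = "NA") -> None:
    out = data.y.astype(object)
    out[~data.mask] = missing_token
    pd.DataFrame(out, columns=list(data.item_names())).to_csv(path, index=False)


def read_ising_matrix(path, tol: float = 1e-8) -> IsingMatrix:
    df = pd.read_csv(path)
    a = df.to_numpy(dtype=float)
    return IsingMatrix.from_array(a, tol=tol, items=tuple(df.columns))


def write_ising_matrix(S: IsingMatrix, path) -> None:
    pd.DataFrame(S.values, columns=list(S.item_names())).to_csv(path, index=False)
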