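"""The universal input container: p responses plus a scalar covariate, with CSV I/O.

A :class:`LabeledSample` holds ``n`` i.i.d. tuples ``(Y_1i, ..., Y_pi, Z_i)``.
All estimators in the package condition on the scalar covariate ``Z``.
Files are plain CSV with header columns ``Y1 ... Yp, Z``.
"""

from __future__ import annotations

import warnings
from dataclasses import InitVar, dataclass

import numpy as np
import pandas as pd

from .exceptions import TiesWarning

__all__ = ["LabeledSample", "read_sample", "write_sample"]


@dataclass(frozen=True)
class LabeledSample:
    """``n`` observations of ``p`` continuous responses and a scalar covariate.

    Parameters
    ----------
    Y : (n, p) array_like
        Response matrix; the theory assumes continuous marginals, so tied
        values trigger a :class:`~condtau.exceptions.TiesWarning` (the strict
        concordance indicator is conservative under ties).
    Z : (n,) array_like
        Conditioning covariate.
    """

    Y: np.ndarray
    Z: np.ndarray
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        Z = np.asarray(self.Z, dtype=float).ravel()
        if Y.ndim != 2:
            raise ValueError("Y must be a 2-d (n, p) array")
        n, p = Y.shape
        if p < 2:
            raise ValueError(f"need at least two response columns, got p={p}")
        if n < 2:
            raise ValueError(f"need at least two observations, got n={n}")
        if Z.shape[0] != n:
            raise ValueError(f"Z has length {Z.shape[0]}, expected n={n}")
        if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(Z))):
            raise ValueError("Y and Z must be finite with no missing values")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "Z", Z)
        if any(np.unique(Y[:, j]).size < n for j in range(p)):
            warnings.warn(
                "ties detected in Y; strict-inequality concordance counts are "
                "conservative",
                TiesWarning,
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    def drop(self, i: int) -> "LabeledSample":
        """Leave-one-out subsample with observation ``i`` removed (no re-validation)."""
        keep = np.arange(self.n) != i
        return LabeledSample(self.Y[keep], self.Z[keep], validate=False)


def read_sample(path) -> LabeledSample:
    """Read a :class:`LabeledSample` from a CSV file with columns ``Y1..Yp, Z``."""
    df = pd.read_csv(path)
    if "Z" not in df.columns:
        raise ValueError(f"{path}: missing required column 'Z'")
    p = 0
    while f"Y{p + 1}" in df.columns:
        p += 1
    if p < 2:
        raise ValueError(f"{path}: expected consecutive columns Y1..Yp with p >= 2")
    cols = [f"Y{j + 1}" for j in range(p)] + ["Z"]
    sub = df[cols]
    if sub.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed")
    try:
        values = sub.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in columns {cols}") from exc
    return LabeledSample(values[:, :p], values[:, p])


def write_sample(sample: LabeledSample, path) -> None:
    """Write a :class:`LabeledSample` to CSV (columns ``Y1..Yp, Z``, row order kept)."""
    data = {f"Y{j + 1}": sample.Y[:, j] for j in range(sample.p)}
    data["Z"] = sample.Z
    pd.DataFrame(data).to_csv(path, index=False)
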