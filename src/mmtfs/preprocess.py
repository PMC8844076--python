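"""Per-feature normalization and optional covariate residualization.

Two schemes, assigned per modality block:

* min-max: ``x~ = (x - min) / (max - min + eps)`` — bounded continuous
  measures (default for the imaging block);
* z-score: ``x~ = (x - mean) / sqrt(var_{N-1} + eps)`` — the small ``eps``
  sits inside the square root, so constant columns map to 0 instead of
  dividing by zero (default for the genotype block).

Parameters are estimated on training samples only and frozen; applying
frozen parameters to unseen values may fall outside the training range
(no clipping), which is the correct behaviour inside cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .data import MultiModalDataset
from .errors import ConfigurationError, DataFormatError

DEFAULT_EPS = 1e-8
DEFAULT_SCHEMES = {"imaging": "minmax", "snp": "zscore"}


@dataclass
class NormalizationParams:
    """Frozen per-feature statistics for one block of columns."""

    scheme: str                      # "minmax" | "zscore"
    eps: float
    stat_a: np.ndarray               # per-feature min (minmax) or mean (zscore)
    stat_b: np.ndarray               # per-feature max (minmax) or sample SD (zscore)

    def __post_init__(self) -> None:
        if self.scheme not in ("minmax", "zscore"):
            raise ConfigurationError(f"unknown normalization scheme {self.scheme!r}")
        if self.eps <= 0:
            raise ConfigurationError("epsilon must be positive")


def _check_finite(values: np.ndarray, context: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        j = int(np.argwhere(~np.isfinite(values).reshape(values.shape[0], -1).all(axis=0)).ravel()[0]) \
            if values.ndim == 2 else 0
        raise DataFormatError(f"non-finite input in {context} (feature column {j})")
    return np.atleast_2d(values.T).T if values.ndim == 1 else values


def fit_minmax(values: np.ndarray, eps: float = DEFAULT_EPS) -> NormalizationParams:
    """Estimate per-column min/max on training values (rows = samples)."""
    values = _check_finite(values, "fit_minmax")
    if values.shape[0] < 1:
        raise ConfigurationError("min-max fit needs at least one training value")
    return NormalizationParams("minmax", eps, values.min(axis=0), values.max(axis=0))


def apply_minmax(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - params.stat_a) / (params.stat_b - params.stat_a + params.eps)


def fit_zscore(values: np.ndarray, eps: float = DEFAULT_EPS) -> NormalizationParams:
    """Estimate per-column mean and N-1 sample SD on training values."""
    values = _check_finite(values, "fit_zscore")
    if values.shape[0] < 2:
        raise ConfigurationError("z-score fit needs >= 2 training values (N-1 variance)")
    return NormalizationParams("zscore", eps, values.mean(axis=0), values.std(axis=0, ddof=1))


def apply_zscore(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - params.stat_a) / np.sqrt(params.stat_b**2 + params.eps)


_FIT = {"minmax": fit_minmax, "zscore": fit_zscore}
_APPLY = {"minmax": apply_minmax, "zscore": apply_zscore}


def fit_normalization(
    ds: MultiModalDataset,
    schemes: dict[str, str] | None = None,
    eps: float = DEFAULT_EPS,
) -> dict[str, NormalizationParams]:
    """Fit one :class:`NormalizationParams` per modality block."""
    schemes = dict(DEFAULT_SCHEMES) if schemes is None else schemes
    params: dict[str, NormalizationParams] = {}
    for name in ds.block_names:
        if name not in schemes:
            raise ConfigurationError(f"no normalization scheme assigned to block {name!r}")
        if schemes[name] not in _FIT:
            raise ConfigurationError(f"unknown scheme {schemes[name]!r} for block {name!r}")
        params[name] = _FIT[schemes[name]](ds.block(name), eps)
    return params


def apply_normalization(
    ds: MultiModalDataset, params: dict[str, NormalizationParams]
) -> MultiModalDataset:
    """Transform every block with its frozen parameters; metadata unchanged."""
    X = ds.X.copy()
    for name in ds.block_names:
        if name not in params:
            raise ConfigurationError(f"no fitted parameters for block {name!r}")
        s = ds.block_slice(name)
        X[:, s] = _APPLY[params[name].scheme](ds.X[:, s], params[name])
    return ds.with_matrix(X)


def normalize_dataset(
    ds: MultiModalDataset,
    schemes: dict[str, str] | None = None,
    eps: float = DEFAULT_EPS,
) -> tuple[MultiModalDataset, dict[str, NormalizationParams]]:
    """Fit-and-apply convenience wrapper (fit and transform on the same data)."""
    params = fit_normalization(ds, schemes, eps)
    return apply_normalization(ds, params), params


# ---------------------------------------------------------------------------
# Covariate residualization
# ---------------------------------------------------------------------------

def residualize_covariates(
    ds: MultiModalDataset, covariates: np.ndarray, covariate_names: list[str] | None = None
) -> MultiModalDataset:
    """Replace every feature by its OLS residual on covariates + intercept.

    Used on real cohorts to pre-adjust morphometric measures for nuisance
    variables (age, sex, handedness, education, intracranial volume);
    categorical covariates must arrive numerically encoded.
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != ds.N:
        raise ConfigurationError(f"covariate table has {C.shape[0]} rows for {ds.N} samples")
    if not np.isfinite(C).all():
        raise DataFormatError("non-finite covariate value")
    names = covariate_names or [f"cov{j}" for j in range(C.shape[1])]
    design = np.hstack([np.ones((ds.N, 1)), C])
    # QR with pivoting exposes (near-)collinear columns by tiny R diagonals
    _, R, piv = linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    if (diag <= tol).any():
        bad = [piv[i] for i in np.where(diag <= tol)[0]]
        bad_names = ["intercept" if j == 0 else names[j - 1] for j in bad]
        raise ConfigurationError(f"rank-deficient covariate design; collinear columns: {bad_names}")
    beta, *_ = np.linalg.lstsq(design, ds.X, rcond=None)
    return ds.with_matrix(ds.X - design @ beta)
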