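"""Covariate preparation: transforms raw site variables into model inputs.

Raw habitat variables arrive in four inter-correlated blocks (habitat
structure, water chemistry, hydrology, landscape).  Each block is reduced to
its first principal component; the PC1 score per site then enters the
abundance model as a single composite gradient.  Waterbody area and
nearest-neighbour distance are log10-transformed; everything is standardised
to z-scores so coefficient magnitudes are directly comparable.

PC orientation is arbitrary, so each block carries a sign *anchor*: a named
variable whose loading is forced to a chosen sign (e.g. the hydrology axis is
oriented so that % days connected loads negative — positive scores then mean
disconnected/isolated waterbodies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .survey import SiteTable, SurveyDataset, pearson_r

__all__ = [
    "PreparedCovariates",
    "PcaResult",
    "PrepConfig",
    "log10_positive",
    "zscore",
    "impute_mean",
    "pc1",
    "screen_correlations",
    "prepare_covariates",
    "DEFAULT_ANCHORS",
]

#: default PC1 sign anchors per block: (variable, required loading sign)
DEFAULT_ANCHORS: dict[str, tuple[str, int]] = {
    "hydrology": ("pct_connected", -1),
    "landscape": ("forest", -1),
}


def log10_positive(values) -> np.ndarray:
    """Elementwise base-10 logarithm of strictly positive values."""
    x = np.asarray(values, dtype=float)
    bad = ~(x > 0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad.ravel())[0])
        raise ValidationError(f"log10 requires positive values; offending index {idx}")
    return np.log10(x)


def zscore(values) -> np.ndarray:
    """Standardise to mean 0, sample sd 1 over non-missing entries.

    NaN entries are ignored when computing the mean/sd and stay NaN in the
    output.  Raises on zero variance or fewer than 2 non-missing values.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValidationError("zscore needs at least 2 non-missing values")
    m = x[obs].mean()
    s = x[obs].std(ddof=1)
    if s == 0:
        raise ValidationError("zscore undefined for a zero-variance vector")
    out = np.full_like(x, np.nan)
    out[obs] = (x[obs] - m) / s
    return out


def impute_mean(values) -> np.ndarray:
    """Replace missing (NaN) entries by the mean of the non-missing entries."""
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if not obs.any():
        raise ValidationError("cannot impute an all-missing vector")
    out = x.copy()
    out[~obs] = x[obs].mean()
    return out


@dataclass
class PcaResult:
    """First principal component of one covariate block."""

    loadings: pd.Series           # variable -> loading on PC1
    scores: pd.Series             # site -> PC1 score
    prop_variance: float          # share of total variance on PC1
    anchor: tuple[str, int] | None = None
    eigenvalues: np.ndarray | None = None


def pc1(block: pd.DataFrame, anchor: tuple[str, int] | None = None,
        scale: bool = True) -> PcaResult:
    """First principal component of a sites x variables block.

    By default the decomposition is of the *correlation* matrix (variables
    centered and scaled), appropriate when a block mixes units; pass
    ``scale=False`` for the covariance matrix.  If `anchor` is given as
    ``(variable, sign)`` the eigenvector is flipped, if necessary, so that
    variable's loading carries the requested sign.
    """
    if block.shape[1] < 2 or block.shape[0] < 3:
        raise ValidationError("pc1 needs >= 2 variables and >= 3 sites")
    X = block.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("pc1 does not accept missing values; impute first")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        name = block.columns[int(np.argmax(sd == 0))]
        raise ValidationError(f"zero-variance column {name!r} in PCA block")
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    v = evecs[:, 0]
    if anchor is not None:
        var, sign = anchor
        if var not in block.columns:
            raise ValidationError(f"anchor variable {var!r} not in block")
        load = v[list(block.columns).index(var)]
        if load * sign < 0:
            v = -v
    elif v[np.argmax(np.abs(v))] < 0:  # deterministic fallback orientation
        v = -v
    scores = Xc @ v
    return PcaResult(
        loadings=pd.Series(v, index=block.columns),
        scores=pd.Series(scores, index=block.index),
        prop_variance=float(evals[0] / evals.sum()),
        anchor=anchor,
        eigenvalues=evals,
    )


def screen_correlations(columns: Mapping[str, Sequence[float]],
                        threshold: float = 0.7) -> list[tuple[str, str, float]]:
    """All unordered pairs of named vectors with |r| >= threshold.

    Returns (name_a, name_b, r) sorted by |r| descending; self-pairs are
    never reported.  The default threshold 0.7 is the conventional cutoff
    for flagging collinear covariates.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    names = list(columns)
    hits = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            r = pearson_r(columns[names[a]], columns[names[b]])
            if abs(r) >= threshold:
                hits.append((names[a], names[b], r))
    hits.sort(key=lambda t: -abs(t[2]))
    return hits


# ---------------------------------------------------------------------------
# End-to-end preparation
# ---------------------------------------------------------------------------

@dataclass
class PrepConfig:
    """Switches for covariate preparation.

    anchors
        Per-block (variable, sign) pairs orienting each PC1.
    scale_pca
        Correlation-matrix PCA when True (default), covariance when False.
    impute_chemistry
        Mean-impute missing chemistry readings before PCA.
    rescore_pc1
        Re-standardise PC1 scores to z-scores before they enter the model so
        their coefficient scale matches the other covariates.
    """

    anchors: dict[str, tuple[str, int]] = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    scale_pca: bool = True
    impute_chemistry: bool = True
    rescore_pc1: bool = True
    screen_threshold: float = 0.7


@dataclass
class PreparedCovariates:
    """Standardised design values entering the abundance and detection models.

    ``site`` maps a covariate name (area, distance, fish, hydrology, habitat,
    water, landscape) to a z-scored per-site vector aligned with ``site_ids``.
    ``days_z`` and ``temp_z`` are the z-scored survey-level detection
    covariates, standardised jointly over all site x survey cells.
    """

    site_ids: list[str]
    site: dict[str, np.ndarray]
    days_z: np.ndarray | None = None
    temp_z: np.ndarray | None = None
    pca: dict[str, PcaResult] = field(default_factory=dict)
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        J = len(self.site_ids)
        for name, v in self.site.items():
            v = np.asarray(v, float)
            self.site[name] = v
            if v.shape != (J,):
                raise ValidationError(f"site covariate {name!r} has shape {v.shape}, want ({J},)")
            obs = v[~np.isnan(v)]
            if obs.size and (abs(obs.mean()) > 1e-9 or abs(obs.std(ddof=1) - 1) > 1e-9):
                raise ValidationError(f"site covariate {name!r} is not z-scored")

    def design_matrix(self, covariates: Sequence[str]) -> np.ndarray:
        """(n_sites, 1 + len(covariates)) matrix with a leading intercept column."""
        cols = [np.ones(len(self.site_ids))]
        for name in covariates:
            if name not in self.site:
                raise KeyError(f"unknown covariate {name!r}; have {sorted(self.site)}")
            cols.append(self.site[name])
        return np.column_stack(cols)


_BLOCK_TO_COVARIATE = {"hydrology": "hydrology", "habitat": "habitat",
                       "chemistry": "water", "landscape": "landscape"}


def prepare_covariates(sites: SiteTable, dataset: SurveyDataset | None = None,
                       config: PrepConfig | None = None) -> PreparedCovariates:
    """Build the full standardized design from a raw site table.

    Applies log10 to area and nearest-neighbour distance, mean imputation to
    chemistry, per-block anchored PC1, and z-scoring throughout.  If a
    dataset is supplied its Days and Temp covariates are z-scored jointly
    over all site x survey cells.
    """
    cfg = config or PrepConfig()
    d = sites.data
    out: dict[str, np.ndarray] = {}
    pca: dict[str, PcaResult] = {}

    if "sampled_area_m2" in d:
        out["area"] = zscore(log10_positive(d["sampled_area_m2"].to_numpy(float)))
    if "nn_distance_m" in d:
        out["distance"] = zscore(log10_positive(d["nn_distance_m"].to_numpy(float)))
    if "large_fish_richness" in d:
        out["fish"] = zscore(d["large_fish_richness"].to_numpy(float))

    for cat, cols in sites.blocks.items():
        block = d[cols].astype(float)
        if cat == "chemistry" and cfg.impute_chemistry:
            block = block.apply(lambda c: pd.Series(impute_mean(c.to_numpy()),
                                                    index=c.index))
        res = pc1(block, anchor=cfg.anchors.get(cat), scale=cfg.scale_pca)
        pca[cat] = res
        scores = res.scores.to_numpy()
        name = _BLOCK_TO_COVARIATE.get(cat, cat)
        out[name] = zscore(scores) if cfg.rescore_pc1 else scores

    days_z = temp_z = None
    if dataset is not None:
        days_z = (dataset.days - dataset.days.mean()) / dataset.days.std(ddof=1)
        temp_z = (dataset.water_temp - dataset.water_temp.mean()) / dataset.water_temp.std(ddof=1)

    flagged = screen_correlations({k: v for k, v in out.items()},
                                  cfg.screen_threshold)
    return PreparedCovariates(
        site_ids=sites.site_ids, site=out, days_z=days_z, temp_z=temp_z,
        pca=pca, flagged_pairs=flagged,
    )
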