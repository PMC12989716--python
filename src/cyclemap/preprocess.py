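"""Normalization and non-proliferative-cell filtering.

Two scikit-learn-style estimators operating on cohort tables (DataFrames
with identity columns plus marker-intensity columns):

- :class:`SampleZScorer` — z-scores every marker within each tissue sample,
  removing sample-level batch effects so intensities are comparable across
  samples.
- :class:`ProliferationGate` — fits a two-component univariate Gaussian
  mixture to a proliferation marker (pRB by default) and removes cells
  assigned to the lower-mean (non-proliferating, pRB-low) component.

Module-level :func:`zscore_normalize` and :func:`filter_nonproliferative`
are thin wrappers.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from .synthetic import feature_columns

__all__ = [
    "SampleZScorer",
    "ProliferationGate",
    "zscore_normalize",
    "filter_nonproliferative",
]

logger = logging.getLogger(__name__)

NORMALIZED_ATTR = "cyclemap_normalized"


def _check_table(table: pd.DataFrame) -> list[str]:
    if "sample_id" not in table.columns:
        raise ValueError("table must have a 'sample_id' column")
    if (table["sample_id"].astype(str) == "").any():
        raise ValueError("sample_id must be non-empty")
    feats = feature_columns(table)
    if table[feats].isna().any().any():
        raise ValueError("marker columns contain missing values")
    return feats


class SampleZScorer(BaseEstimator, TransformerMixin):
    """Per-sample, per-marker z-scoring of a cohort table.

    Within each sample every marker is transformed to ``(x - mean) / sd``.
    The population (``ddof=0``) standard deviation is used so that the output
    is a pure function of the input values.  Zero-variance markers within a
    sample map to 0 with a logged warning.  ``global_scaling=True`` computes
    one mean/sd across the whole table instead (which does *not* remove
    sample batch effects).

    Attributes
    ----------
    means_, sds_ : pd.DataFrame
        Per-sample (rows) per-marker (columns) statistics after :meth:`fit`.
    """

    def __init__(self, global_scaling: bool = False):
        self.global_scaling = global_scaling

    def fit(self, table: pd.DataFrame, y=None) -> "SampleZScorer":
        feats = _check_table(table)
        if self.global_scaling:
            grp = table[feats].agg(["mean"])
            self.means_ = grp.loc[["mean"]].rename(index={"mean": "__global__"})
            self.sds_ = pd.DataFrame(
                [table[feats].std(ddof=0)], index=["__global__"]
            )
        else:
            sizes = table.groupby("sample_id").size()
            small = sizes[sizes < 2]
            if len(small):
                raise ValueError(
                    f"samples with fewer than 2 cells cannot be z-scored: {list(small.index)}"
                )
            g = table.groupby("sample_id")[feats]
            self.means_ = g.mean()
            self.sds_ = g.std(ddof=0)
        self.feature_names_in_ = feats
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        feats = self.feature_names_in_
        out = table.copy()
        if self.global_scaling:
            mu = self.means_.iloc[0]
            sd = self.sds_.iloc[0]
            zero = sd == 0
            sd = sd.mask(zero, 1.0)
            out[feats] = (out[feats] - mu) / sd
            out.loc[:, np.array(feats)[zero.to_numpy()]] = 0.0
            if zero.any():
                logger.warning("zero-variance markers mapped to 0: %s", list(sd.index[zero]))
        else:
            mu = self.means_.loc[out["sample_id"]].to_numpy()
            sd = self.sds_.loc[out["sample_id"]].to_numpy()
            zero = sd == 0
            if zero.any():
                logger.warning(
                    "zero-variance marker/sample pairs mapped to 0 (%d)", int(zero.sum())
                )
            sd = np.where(zero, 1.0, sd)
            z = (out[feats].to_numpy() - mu) / sd
            z[zero] = 0.0
            out[feats] = z
        out.attrs[NORMALIZED_ATTR] = True
        return out


class ProliferationGate(BaseEstimator):
    """Gaussian-mixture gate removing non-proliferating (marker-low) cells.

    Fits a two-component univariate Gaussian mixture to one marker, pooled
    over all cells.  Cells with posterior probability > ``threshold`` of
    belonging to the lower-mean component are classed non-proliferative.  If
    either mixture weight falls below ``weight_floor`` the fit is declared
    degenerate and the gate passes everything through.  The mixture is fit on
    log intensities for raw tables and on the values directly once the table
    is z-scored.

    Attributes
    ----------
    means_, sds_, weights_ : ndarray of shape (2,), low component first.
    degenerate_ : bool — weight floor triggered, gate passes through.
    """

    def __init__(self, marker: str = "pRB", threshold: float = 0.5,
                 weight_floor: float = 0.02, random_state: int = 0):
        self.marker = marker
        self.threshold = threshold
        self.weight_floor = weight_floor
        self.random_state = random_state

    def _values(self, table: pd.DataFrame) -> np.ndarray:
        if self.marker not in table.columns:
            raise ValueError(f"marker {self.marker!r} not in table")
        x = table[self.marker].to_numpy(dtype=float)
        if not table.attrs.get(NORMALIZED_ATTR, False):
            if (x <= 0).any():
                raise ValueError("raw intensities must be positive to take logs")
            x = np.log(x)
        return x

    def fit(self, table: pd.DataFrame, y=None) -> "ProliferationGate":
        x = self._values(table)
        q = np.quantile(x, [0.25, 0.75])
        gmm = GaussianMixture(
            n_components=2,
            means_init=q.reshape(-1, 1),
            random_state=self.random_state,
            max_iter=500,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gmm.fit(x.reshape(-1, 1))
        if not gmm.converged_:
            raise RuntimeError(
                f"mixture fit on {self.marker!r} did not converge "
                f"(n={x.size}, lower_bound={gmm.lower_bound_:.4g})"
            )
        order = np.argsort(gmm.means_.ravel())
        self.means_ = gmm.means_.ravel()[order]
        self.sds_ = np.sqrt(gmm.covariances_.ravel()[order])
        self.weights_ = gmm.weights_[order]
        self._gmm = gmm
        self._low_component = int(order[0])
        self.degenerate_ = bool(self.weights_.min() < self.weight_floor)
        if self.degenerate_:
            logger.warning(
                "mixture weight %.3g below floor %.3g: gate passes all cells through",
                self.weights_.min(), self.weight_floor,
            )
        # unimodality heuristic: a genuine low/high split leaves a density
        # valley between the component means; no valley => warn
        grid = np.linspace(self.means_[0], self.means_[1], 256)
        dens = np.exp(self._gmm.score_samples(grid.reshape(-1, 1)))
        valley = dens[1:-1].min() if len(grid) > 2 else dens.min()
        peaks = min(dens[0], dens[-1])
        if peaks > 0 and valley > 0.8 * peaks:
            warnings.warn(
                f"{self.marker!r} looks unimodal (no density valley between "
                "components); the gate will still remove the lower-mean "
                "pseudo-component",
                UserWarning,
            )
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """+1 for proliferative (kept), -1 for non-proliferative cells."""
        x = self._values(table)
        if self.degenerate_:
            return np.ones(x.size, dtype=int)
        post_low = self._gmm.predict_proba(x.reshape(-1, 1))[:, self._low_component]
        return np.where(post_low > self.threshold, -1, 1)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """The kept (proliferative) subset, order preserved."""
        return table[self.predict(table) == 1]

    def split(self, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(kept, removed) partition of the table, order preserved."""
        keep = self.predict(table) == 1
        return table[keep], table[~keep]

    def summary(self) -> dict:
        return {
            "marker": self.marker,
            "means": list(map(float, self.means_)),
            "sds": list(map(float, self.sds_)),
            "weights": list(map(float, self.weights_)),
            "degenerate": self.degenerate_,
            "threshold": self.threshold,
        }


def zscore_normalize(table: pd.DataFrame, global_scaling: bool = False) -> pd.DataFrame:
    """Z-score every marker within each sample (see :class:`SampleZScorer`)."""
    return SampleZScorer(global_scaling=global_scaling).fit_transform(table)


def filter_nonproliferative(
    table: pd.DataFrame, marker: str = "pRB", **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Remove marker-low cells via a 2-component Gaussian mixture.

    Returns ``(kept, removed, mixture_summary)``.
    """
    gate = ProliferationGate(marker=marker, **kwargs).fit(table)
    kept, removed = gate.split(table)
    return kept, removed, gate.summary()
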