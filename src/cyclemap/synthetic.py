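"""Synthetic single-cell marker-intensity cohorts with a planted cell cycle.

Emulates multiplexed-immunofluorescence feature tables from liver tissue
microarrays: one row per segmented cell, one intensity column per protein
marker, with per-sample batch effects and log-normal measurement noise.

Each cell lives on a branched one-dimensional manifold parameterized by a
pseudotime in [0, 1):

- the **canonical** branch traverses G1 -> S -> G2 -> M and wraps back to G1;
- the **endocycle** branch shares G1 -> S -> G2, then diverges after G2 into
  an endocycle segment (whole-genome duplication without mitosis) that
  re-enters G1;
- the **nonproliferative** branch is a flat out-of-cycle state with low pRB.

Marker mean log-intensities are plateaus per phase with smooth transitions,
defined by a versioned panel profile (see ``data/default_panel.json``).  The
default panel encodes canonical cell cycle biology (Cyclin D1 peaking in G1,
Cyclin E1/E2 in S, CDK1 in G2/M, CDK-inhibitors p16/p21/p27 high out of
cycle) and the endocycle signature: RAIDD, Wee1 and CDK2 elevated relative to
canonical G2, CDK1 suppressed, and RAIDD declining toward the branch exit as
stress resolves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "PHASES",
    "PanelProfile",
    "CohortSpec",
    "default_panel",
    "generate_cohort",
]

#: the 17-protein cell cycle panel, in fixed column order
MARKERS = (
    "pRB", "AKT", "p16", "p21", "RB", "CDK6", "Cyclin E2", "Cyclin D1",
    "CDK2", "Wee1", "Cyclin E1", "p27", "Smad4", "CDK1", "RAIDD", "MDM2",
    "cMyc",
)

#: planted phase labels
PHASES = ("G1", "S", "G2", "M", "endocycle", "nonproliferative")

ID_COLUMNS = ("cell_id", "sample_id", "condition")
TRUTH_COLUMNS = ("true_branch", "true_phase", "true_pseudotime")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


class PanelProfile:
    """Mean-intensity model for every marker over (branch, pseudotime).

    Parameters come from a JSON panel document; :func:`default_panel` loads
    the packaged default.  Mean intensities are ``exp`` of piecewise-smooth
    log-level curves, so they are strictly positive everywhere.
    """

    def __init__(self, doc: dict):
        self.doc = doc
        self.noise_sd = float(doc["noise_sd"])
        self.batch_shift_sd = float(doc["batch_shift_sd"])
        self.batch_scale_sd = float(doc.get("batch_scale_sd", 0.0))
        self.segments = {k: tuple(v) for k, v in doc["phase_segments"].items()}
        self.endo_segment = tuple(doc["endocycle_segment"])
        self.halfwidth = float(doc["transition_halfwidth"])
        self.endo_peak = float(doc["endocycle_peak_time"])
        self.endo_exit_blend = float(doc["endocycle_exit_blend"])
        self.log_levels = doc["log_levels"]
        missing = set(MARKERS) - set(self.log_levels)
        if missing:
            raise ValueError(f"panel missing markers: {sorted(missing)}")
        for m in MARKERS:
            if set(self.log_levels[m]) != set(PHASES):
                raise ValueError(f"panel marker {m!r} must give a level per phase")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PanelProfile":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_file(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.doc, fh, indent=2)

    # -- mean curves -------------------------------------------------------

    def _canonical_log(self, marker: str, t: np.ndarray) -> np.ndarray:
        """Plateau-per-phase curve with smoothstep blends at phase boundaries,
        periodic across the M -> G1 wrap."""
        lv = self.log_levels[marker]
        levels = np.array([lv["G1"], lv["S"], lv["G2"], lv["M"]])
        bounds = np.array([self.segments["S"][0], self.segments["G2"][0], self.segments["M"][0]])
        t = np.asarray(t, dtype=float) % 1.0
        out = levels[np.searchsorted(bounds, t, side="right")]
        w = self.halfwidth
        for i, b in enumerate(bounds):
            mask = np.abs(t - b) < w
            if mask.any():
                s = _smoothstep((t[mask] - b + w) / (2 * w))
                out[mask] = (1 - s) * levels[i] + s * levels[i + 1]
        # periodic M -> G1 wrap at t = 0 (== 1)
        dist = np.where(t > 0.5, t - 1.0, t)
        mask = np.abs(dist) < w
        if mask.any():
            s = _smoothstep((dist[mask] + w) / (2 * w))
            out[mask] = (1 - s) * levels[3] + s * levels[0]
        return out

    def _endocycle_log(self, marker: str, t: np.ndarray) -> np.ndarray:
        """Shares G1/S/G2 with the canonical branch; after G2 rises to the
        endocycle level and relaxes toward G1 re-entry at the branch exit."""
        lv = self.log_levels[marker]
        t = np.asarray(t, dtype=float) % 1.0
        out = self._canonical_log(marker, t)
        lo, hi = self.endo_segment
        mask = t >= lo
        if mask.any():
            exit_level = (
                self.endo_exit_blend * lv["endocycle"]
                + (1 - self.endo_exit_blend) * lv["G1"]
            )
            xp = [lo, self.endo_peak, hi]
            fp = [lv["G2"], lv["endocycle"], exit_level]
            out[mask] = np.interp(t[mask], xp, fp)
        return out

    def mean_log(self, marker: str, branch: str, t: np.ndarray) -> np.ndarray:
        """Mean log-intensity of ``marker`` at pseudotime ``t`` on ``branch``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if branch == "canonical":
            return self._canonical_log(marker, t)
        if branch == "endocycle":
            return self._endocycle_log(marker, t)
        if branch == "nonproliferative":
            return np.full(t.shape, self.log_levels[marker]["nonproliferative"])
        raise ValueError(f"unknown branch {branch!r}")

    def mean_intensity(self, marker: str, branch: str, t: np.ndarray) -> np.ndarray:
        return np.exp(self.mean_log(marker, branch, t))

    # -- invariants --------------------------------------------------------

    def validate(self, grid: int = 256) -> None:
        """Check the planted biology the rest of the pipeline relies on.

        Raises ``ValueError`` if the endocycle signature (RAIDD/Wee1/CDK2 up,
        CDK1 down, RAIDD declining toward exit) or the pRB proliferation
        contrast is violated.
        """
        lo, hi = self.endo_segment
        t_endo = np.linspace(lo, hi, grid, endpoint=False)
        g2 = self.segments["G2"]
        t_g2 = np.linspace(g2[0], g2[1], grid, endpoint=False)
        t_m = np.linspace(self.segments["M"][0], self.segments["M"][1], grid, endpoint=False)

        def endo_mean(m):
            return self.mean_log(m, "endocycle", t_endo).mean()

        def g2_mean(m):
            return self.mean_log(m, "canonical", t_g2).mean()

        for m in ("RAIDD", "Wee1", "CDK2"):
            if not endo_mean(m) > g2_mean(m):
                raise ValueError(f"{m} must be higher on the endocycle branch than canonical G2")
        g2m_cdk1 = np.concatenate(
            [self.mean_log("CDK1", "canonical", t_g2), self.mean_log("CDK1", "canonical", t_m)]
        ).mean()
        if not endo_mean("CDK1") < g2m_cdk1:
            raise ValueError("CDK1 must be lower on the endocycle branch than canonical G2/M")
        tail = np.linspace(self.endo_peak, hi, grid)
        raidd_tail = self.mean_log("RAIDD", "endocycle", tail)
        if not np.all(np.diff(raidd_tail) <= 1e-12) or raidd_tail[0] <= raidd_tail[-1]:
            raise ValueError("RAIDD must decline toward the endocycle branch exit")
        t_all = np.linspace(0, 1, grid, endpoint=False)
        prb_np = self.mean_log("pRB", "nonproliferative", t_all).mean()
        for branch in ("canonical", "endocycle"):
            if not prb_np < self.mean_log("pRB", branch, t_all).mean():
                raise ValueError("nonproliferative pRB must be below proliferative branches")


def default_panel() -> PanelProfile:
    """The packaged default panel; satisfies every :class:`PanelProfile` invariant."""
    with resources.files("cyclemap.data").joinpath("default_panel.json").open() as fh:
        panel = PanelProfile(json.load(fh))
    panel.validate()
    return panel


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: samples per condition, cells per sample, composition.

    Defaults emulate the study design: 26 steatohepatitis (MASH) tissue
    samples plus healthy controls, ~30% of cells out of cycle, and a higher
    endocycle-branch probability in MASH than in healthy liver.
    """

    n_samples: dict = field(default_factory=lambda: {"healthy": 8, "MASH": 26})
    cells_per_sample: int = 300
    phase_occupancy: dict = field(
        default_factory=lambda: {"G1": 0.4, "S": 0.25, "G2": 0.2, "M": 0.15}
    )
    endocycle_prob: dict = field(default_factory=lambda: {"healthy": 0.02, "MASH": 0.10})
    nonproliferative_fraction: float = 0.3
    compartments: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        occ = self.phase_occupancy
        if set(occ) != {"G1", "S", "G2", "M"}:
            raise ValueError("phase_occupancy must cover exactly G1, S, G2, M")
        if any(p < 0 for p in occ.values()) or abs(sum(occ.values()) - 1.0) > 1e-9:
            raise ValueError("phase_occupancy must be non-negative and sum to 1")
        for cond, p in self.endocycle_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"endocycle_prob[{cond!r}] must be in [0, 1]")
        if not 0.0 <= self.nonproliferative_fraction < 1.0:
            raise ValueError("nonproliferative_fraction must be in [0, 1)")
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if set(self.n_samples) != set(self.endocycle_prob):
            raise ValueError("n_samples and endocycle_prob must share conditions")


def generate_cohort(spec: CohortSpec = CohortSpec(),
                    panel: PanelProfile | None = None) -> pd.DataFrame:
    """Simulate a cohort feature table: one row per cell.

    Columns: cell_id, sample_id, condition, true_branch, true_phase,
    true_pseudotime, then one intensity column per marker (two, suffixed
    ``_nuc``/``_cyto``, when ``spec.compartments`` is set).  Intensities are
    ``exp(scale * mean_log + batch_shift + Normal(0, noise_sd))`` with one
    batch shift (and scale) drawn per sample per marker.  Bit-reproducible
    for a fixed ``spec.seed``.
    """
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(spec.seed)
    phases = list(spec.phase_occupancy)
    occ = np.array([spec.phase_occupancy[p] for p in phases])
    seg = panel.segments
    lo_endo, hi_endo = panel.endo_segment

    frames = []
    cell_counter = 0
    for condition in sorted(spec.n_samples):
        p_endo = spec.endocycle_prob[condition]
        for i_sample in range(spec.n_samples[condition]):
            sample_id = f"{condition}_{i_sample + 1:02d}"
            n = spec.cells_per_sample
            u = rng.random(n)
            branch = np.where(
                u < spec.nonproliferative_fraction,
                "nonproliferative",
                np.where(
                    u < spec.nonproliferative_fraction + (1 - spec.nonproliferative_fraction) * p_endo,
                    "endocycle",
                    "canonical",
                ),
            )
            phase = np.empty(n, dtype=object)
            t = np.empty(n)
            m_np = branch == "nonproliferative"
            phase[m_np] = "nonproliferative"
            t[m_np] = rng.random(m_np.sum())
            m_e = branch == "endocycle"
            phase[m_e] = "endocycle"
            t[m_e] = lo_endo + (hi_endo - lo_endo) * rng.random(m_e.sum())
            m_c = branch == "canonical"
            can_phase = rng.choice(phases, size=m_c.sum(), p=occ)
            phase[m_c] = can_phase
            starts = np.array([seg[p][0] for p in can_phase])
            widths = np.array([seg[p][1] - seg[p][0] for p in can_phase])
            t[m_c] = starts + widths * rng.random(m_c.sum())

            cols = {
                "cell_id": np.arange(cell_counter, cell_counter + n),
                "sample_id": sample_id,
                "condition": condition,
                "true_branch": branch,
                "true_phase": phase,
                "true_pseudotime": t,
            }
            cell_counter += n
            shift = rng.normal(0.0, panel.batch_shift_sd, size=len(MARKERS))
            scale = (
                np.exp(rng.normal(0.0, panel.batch_scale_sd, size=len(MARKERS)))
                if panel.batch_scale_sd > 0
                else np.ones(len(MARKERS))
            )
            for j, marker in enumerate(MARKERS):
                mean_log = np.empty(n)
                for br in ("canonical", "endocycle", "nonproliferative"):
                    m = branch == br
                    if m.any():
                        mean_log[m] = panel.mean_log(marker, br, t[m])
                base = scale[j] * mean_log + shift[j]
                if spec.compartments:
                    for comp in ("_nuc", "_cyto"):
                        noise = rng.normal(0.0, panel.noise_sd, size=n) if panel.noise_sd > 0 else 0.0
                        cols[marker + comp] = np.exp(base + noise)
                else:
                    noise = rng.normal(0.0, panel.noise_sd, size=n) if panel.noise_sd > 0 else 0.0
                    cols[marker] = np.exp(base + noise)
            frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Marker-intensity columns of a cohort table, in panel order."""
    cols = []
    for m in MARKERS:
        if m in table.columns:
            cols.append(m)
        for comp in ("_nuc", "_cyto"):
            if m + comp in table.columns:
                cols.append(m + comp)
    if not cols:
        raise ValueError("table contains no recognized marker columns")
    return cols
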