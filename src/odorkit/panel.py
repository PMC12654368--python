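"""Group odor-threshold estimation from ascending-series panel data.

The design is an ascending method of limits in water with a single-bottle
yes/no detection task: each assessor smells a blank and then a 10-fold
dilution series and reports detectability (0/1), free-text descriptors, and
a 0–5 intensity per concentration. The group detection threshold is the
lowest tested concentration at which at least half the panel reports
detection (≥10 of 20 with the standard panel size). Uncertainty comes from
a non-parametric bootstrap over panelists: resample assessors with
replacement, recompute the group threshold per replicate, and take
percentiles of the replicate distribution.

When only per-concentration yes-counts are available (published tables give
marginals, not raw assessor vectors), :func:`reconstruct_monotone` builds
the unique monotone detection matrix consistent with the counts — each
assessor detects everything above their personal sensitivity — which the
ascending-series logic implies. This reconstruction is an assumption and is
flagged in estimate metadata.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: Sentinel concentration for "no tested level met the detection rule".
CENSORED = math.inf


@dataclass
class PanelSession:
    """Assessor × concentration detection data for one compound.

    ``concentrations`` ascend and may start with a blank (0 mg/L);
    ``detection`` is an (n_panelists, n_concentrations) 0/1 matrix.
    Descriptor tallies and intensity ratings are optional side channels.
    """

    concentrations: np.ndarray
    detection: np.ndarray
    compound: str = ""
    descriptors: list[dict[str, int]] = field(default_factory=list)
    intensity: list[list[float]] | None = None
    intensity_precomputed: list[tuple[float, float]] | None = None
    reconstructed: bool = False

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=np.float64)
        self.detection = np.asarray(self.detection)
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.isin(self.detection, (0, 1)).all():
            raise ValueError("detection entries must be 0/1")
        if self.detection.shape[1] != self.concentrations.size:
            raise ValueError("detection columns must match concentrations")

    @property
    def n_panelists(self) -> int:
        return self.detection.shape[0]

    @property
    def counts(self) -> np.ndarray:
        return self.detection.sum(axis=0)


@dataclass
class GroupThresholdEstimate:
    """Point estimate plus bootstrap CI for a group detection threshold."""

    point: float  # mg/L, CENSORED when no level met the rule
    rule_fraction: float
    bootstrap_median: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    B: int | None = None
    seed: int | None = None
    max_tested: float | None = None
    reconstructed: bool = False

    def format_value(self, value: float | None) -> str:
        if value is None:
            return "NA"
        if value == CENSORED:
            return f"> {self.max_tested:g}" if self.max_tested else "> max tested"
        return f"{value:g}"

    def to_dict(self) -> dict:
        return {
            "point_mg_L": self.format_value(self.point),
            "bootstrap_median_mg_L": self.format_value(self.bootstrap_median),
            "ci95_mg_L": [self.format_value(self.ci_low), self.format_value(self.ci_high)],
            "rule_fraction": self.rule_fraction,
            "n_bootstrap": self.B,
            "seed": self.seed,
            "monotone_reconstruction_assumed": self.reconstructed,
        }


def _rule_count(n: int, rule_fraction: float) -> int:
    return int(math.ceil(rule_fraction * n - 1e-9))


def group_threshold(session: PanelSession, rule_fraction: float = 0.5) -> float:
    """Lowest nonzero tested concentration detected by ≥ rule_fraction of the panel.

    Returns :data:`CENSORED` (infinity) when no tested level qualifies;
    callers report that as "> max tested".
    """
    if session.detection.size == 0:
        raise ValueError("empty detection matrix")
    need = _rule_count(session.n_panelists, rule_fraction)
    counts = session.counts
    for j, conc in enumerate(session.concentrations):
        if conc > 0 and counts[j] >= need:
            return float(conc)
    return CENSORED


def reconstruct_monotone(counts, n: int) -> np.ndarray:
    """Unique monotone detection matrix with the given per-concentration counts.

    Assessors are ordered most-sensitive first: assessor *i* detects at
    concentration *j* iff ``i < counts[j]``. Column sums reproduce *counts*
    exactly; every assessor's profile is non-decreasing along the ascending
    series. Decreasing counts are inconsistent with monotone profiles and
    raise — supply the raw detection matrix in that case.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0) or np.any(counts > n):
        raise ValueError("counts must lie in [0, n]")
    if np.any(np.diff(counts) < 0):
        raise ValueError(
            "counts decrease along the ascending series; monotone reconstruction "
            "is impossible — supply the raw per-assessor detection matrix"
        )
    return (np.arange(n)[:, None] < counts[None, :]).astype(np.int64)


def bootstrap_threshold_ci(
    session: PanelSession,
    rule_fraction: float = 0.5,
    B: int = 10000,
    seed: int | None = None,
    level: float = 0.95,
) -> GroupThresholdEstimate:
    """Panelist bootstrap for the group threshold.

    Each replicate resamples the panel with replacement and recomputes the
    group threshold under the same ≥ rule_fraction detection rule. Censored
    replicates sort above every tested concentration. CI endpoints are the
    2.5th/97.5th percentiles of the ordered replicate thresholds, taken as
    inverse-empirical-CDF order statistics (the ceil(p·B)-th smallest, i.e.
    lower-value assignment at probability ties), which keeps endpoints on
    the tested concentration grid. The point estimate is the bootstrap
    median.
    """
    n = session.n_panelists
    need = _rule_count(n, rule_fraction)
    nonzero = session.concentrations > 0
    concs = session.concentrations[nonzero]
    det = session.detection[:, nonzero]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    rep_counts = det[idx].sum(axis=1)  # (B, n_conc)
    qualifies = rep_counts >= need
    any_q = qualifies.any(axis=1)
    first = np.argmax(qualifies, axis=1)
    thresholds = np.where(any_q, concs[first], CENSORED)

    def pct(p: float) -> float:
        k = max(1, math.ceil(p * B))
        return float(np.sort(thresholds)[k - 1])

    lo_p = (1.0 - level) / 2.0
    return GroupThresholdEstimate(
        point=group_threshold(session, rule_fraction),
        rule_fraction=rule_fraction,
        bootstrap_median=pct(0.5),
        ci_low=pct(lo_p),
        ci_high=pct(1.0 - lo_p),
        B=B,
        seed=seed,
        max_tested=float(concs.max()),
        reconstructed=session.reconstructed,
    )


def descriptor_tally(session: PanelSession) -> list[dict[str, int]]:
    """Per-concentration descriptor term → count tallies."""
    return [dict(sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))) for d in session.descriptors]


def intensity_summary(session: PanelSession) -> list[tuple[float, float]]:
    """Mean ± SD (n−1 denominator) of 0–5 intensity ratings per concentration.

    A single rating has undefined SD; 0.0 is reported by convention. Falls
    back to precomputed summaries for sessions built from published tables.
    """
    if session.intensity is not None:
        out = []
        for ratings in session.intensity:
            arr = np.asarray(ratings, dtype=np.float64)
            m = float(arr.mean()) if arr.size else float("nan")
            s = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            out.append((m, s))
        return out
    if session.intensity_precomputed is not None:
        return list(session.intensity_precomputed)
    raise ValueError("session carries no intensity data")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_tally(text: str) -> dict[str, int]:
    tally: dict[str, int] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part or ":" not in part:
            continue
        term, count = part.rsplit(":", 1)
        term = term.strip()
        c = int(count.strip())
        if term.lower() == "none" or c == 0:
            continue
        tally[term] = tally.get(term, 0) + c
    return tally


def session_from_counts(
    concentrations,
    counts,
    n_panelists: int,
    compound: str = "",
    descriptors: list[dict[str, int]] | None = None,
    intensity_precomputed: list[tuple[float, float]] | None = None,
) -> PanelSession:
    """Build a session from marginal yes-counts via monotone reconstruction."""
    return PanelSession(
        concentrations=np.asarray(concentrations, dtype=np.float64),
        detection=reconstruct_monotone(counts, n_panelists),
        compound=compound,
        descriptors=descriptors or [],
        intensity_precomputed=intensity_precomputed,
        reconstructed=True,
    )


def load_count_sessions(path: str | Path) -> dict[str, PanelSession]:
    """Load marginal-count sessions (one compound per block) from CSV.

    Columns: compound, concentration_mg_L, n_detected, n_panelists,
    descriptors ("term: count; ..."), intensity_mean, intensity_sd.
    """
    rows_by_compound: dict[str, list[dict]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rows_by_compound.setdefault(row["compound"], []).append(row)
    sessions = {}
    for compound, rows in rows_by_compound.items():
        rows.sort(key=lambda r: float(r["concentration_mg_L"]))
        n = int(rows[0]["n_panelists"])
        sessions[compound] = session_from_counts(
            concentrations=[float(r["concentration_mg_L"]) for r in rows],
            counts=[int(r["n_detected"]) for r in rows],
            n_panelists=n,
            compound=compound,
            descriptors=[_parse_tally(r.get("descriptors", "")) for r in rows],
            intensity_precomputed=(
                [
                    (float(r["intensity_mean"]), float(r["intensity_sd"]))
                    for r in rows
                ]
                if all((r.get("intensity_mean") or "").strip() for r in rows)
                else None
            ),
        )
    return sessions


def builtin_sessions() -> dict[str, PanelSession]:
    """The packaged worked-example sessions (2-phenylethyl acetate and
    menthyl acetate serial-dilution panels, n = 20)."""
    ref = resources.files("odorkit.data").joinpath("panel_sessions.csv")
    with resources.as_file(ref) as path:
        return load_count_sessions(path)


def load_long_session(path: str | Path, compound: str = "") -> PanelSession:
    """Load a raw long-format session CSV.

    Columns: panelist_id, concentration_mg_L, detected (0/1), descriptors
    (semicolon-separated terms), intensity (0–5).
    """
    cells: dict[tuple[str, float], dict] = {}
    panelists, concs = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid = row["panelist_id"]
            c = float(row["concentration_mg_L"])
            if pid not in panelists:
                panelists.append(pid)
            if c not in concs:
                concs.append(c)
            cells[(pid, c)] = row
    concs = sorted(concs)
    det = np.zeros((len(panelists), len(concs)), dtype=np.int64)
    tallies: list[dict[str, int]] = [{} for _ in concs]
    intensity: list[list[float]] = [[] for _ in concs]
    for i, pid in enumerate(panelists):
        for j, c in enumerate(concs):
            row = cells.get((pid, c))
            if row is None:
                raise ValueError(f"missing cell: panelist {pid} at {c} mg/L")
            det[i, j] = int(row["detected"])
            for term in (row.get("descriptors") or "").split(";"):
                term = term.strip().lower()
                if term:
                    tallies[j][term] = tallies[j].get(term, 0) + 1
            if (row.get("intensity") or "").strip():
                intensity[j].append(float(row["intensity"]))
    return PanelSession(
        concentrations=np.asarray(concs),
        detection=det,
        compound=compound,
        descriptors=tallies,
        intensity=intensity,
    )
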