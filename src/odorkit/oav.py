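"""Odor activity value (OAV) ranking of candidate aroma compounds.

OAV = concentration / odor threshold; a compound with OAV > 1 is present
above its detection threshold and is a plausible contributor to perceived
aroma. This stage combines the contribution classifier's probability, the
threshold regressor's prediction (with its conformal interval mapped back
to mg/L), and measured concentrations into a ranked candidate list,
flagging compounds absent from the training corpus as novel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import models
from .registry import canonicalize


def delog_threshold(y: float, q: float = 0.0) -> tuple[float, float, float]:
    """Map y = -log10(t) back to t mg/L with a multiplicative interval.

    Returns (t, t_lo, t_hi) where the interval is [10^-(y+q), 10^-(y-q)] —
    symmetric on the log scale, asymmetric on the linear scale.
    """
    if q < 0:
        raise ValueError("conformal half-width q must be >= 0")
    t = 10.0 ** (-y)
    return t, 10.0 ** (-(y + q)), 10.0 ** (-(y - q))


def oav(concentration: float, threshold: float) -> float:
    """Dimensionless odor activity value; both inputs in the same units."""
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return concentration / threshold


@dataclass
class CandidateReport:
    """One candidate aroma compound with model outputs and ranking keys."""

    smiles: str
    name: str | None
    p_positive: float
    label: str
    y_pred: float
    threshold_mg_L: float
    threshold_lo: float
    threshold_hi: float
    concentration_mg_L: float | None
    oav: float | None
    novel: bool

    def to_dict(self) -> dict:
        return {
            "smiles": self.smiles,
            "name": self.name,
            "contribution": self.label,
            "p_positive": self.p_positive,
            "predicted_threshold_mg_L": self.threshold_mg_L,
            "threshold_ci95_mg_L": [self.threshold_lo, self.threshold_hi],
            "concentration_mg_L": self.concentration_mg_L,
            "oav": self.oav,
            "novel": self.novel,
        }


def rank_candidates(
    records,
    contribution_artifact,
    threshold_artifact,
    training_smiles: set[str],
    conformal_q: float = 0.0,
) -> tuple[list[CandidateReport], list[dict]]:
    """Score and rank compounds for aroma relevance.

    Novelty = canonical SMILES not in the training corpus (structure match
    only, no name matching). Ranking is (novel first, then OAV descending;
    when concentrations are absent, predicted threshold ascending — most
    potent first). Prediction failures are logged per row and skipped.

    Returns (ranked candidate reports, error records).
    """
    training = {canonicalize(s) for s in training_smiles}
    smiles = [r.smiles_canonical for r in records]
    contrib = models.predict(contribution_artifact, smiles)
    thresh = models.predict(threshold_artifact, smiles)
    reports, errors = [], []
    for rec, c_row, t_row in zip(records, contrib, thresh):
        if "error" in c_row or "error" in t_row:
            errors.append({"smiles": rec.smiles_canonical, "error": c_row.get("error") or t_row.get("error")})
            continue
        y = t_row["y_neglog10_mg_L"]
        t, t_lo, t_hi = delog_threshold(y, conformal_q)
        value = None
        if rec.concentration is not None and rec.concentration > 0:
            value = oav(rec.concentration, t)
        reports.append(
            CandidateReport(
                smiles=rec.smiles_canonical,
                name=rec.name,
                p_positive=c_row["p_positive"],
                label=c_row["label"],
                y_pred=y,
                threshold_mg_L=t,
                threshold_lo=t_lo,
                threshold_hi=t_hi,
                concentration_mg_L=rec.concentration,
                oav=value,
                novel=rec.smiles_canonical not in training,
            )
        )

    def sort_key(r: CandidateReport):
        # novel first; OAV descending when present, else predicted
        # threshold ascending; canonical SMILES as the final total-order key
        oav_key = -r.oav if r.oav is not None else float("inf")
        return (not r.novel, oav_key, r.threshold_mg_L, r.smiles)

    return sorted(reports, key=sort_key), errors


def write_reports(
    reports: list[CandidateReport],
    errors: list[dict],
    out_csv: str | Path,
    out_json: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    """Ranked CSV (positive and negative contributors sectioned) + JSON."""
    import csv as _csv

    with open(out_csv, "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(
            ["section", "smiles", "name", "p_positive", "predicted_threshold_mg_L",
             "threshold_lo_mg_L", "threshold_hi_mg_L", "concentration_mg_L", "oav", "novel"]
        )
        for section in ("positive", "negative"):
            for r in reports:
                if r.label != section:
                    continue
                w.writerow(
                    [section, r.smiles, r.name or "", f"{r.p_positive:.4f}",
                     f"{r.threshold_mg_L:.6g}", f"{r.threshold_lo:.6g}",
                     f"{r.threshold_hi:.6g}",
                     "" if r.concentration_mg_L is None else f"{r.concentration_mg_L:g}",
                     "" if r.oav is None else f"{r.oav:.6g}", int(r.novel)]
                )
    if out_json is not None:
        payload = {
            "candidates": [r.to_dict() for r in reports],
            "errors": errors,
            "provenance": provenance or {},
        }
        with open(out_json, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
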