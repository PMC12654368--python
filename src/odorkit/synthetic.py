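"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage is testable without downloads: molecules come from
template substitution over a scaffold × substituent library (guaranteeing
valid SMILES and controllable Murcko-scaffold group structure), binary
contribution labels follow a structural predicate with optional flip noise
and a target prevalence mirroring the heavy positive-class imbalance of
curated flavor corpora, thresholds follow a linear model on the
physicochemical block with Gaussian noise on the -log10 scale, and panel
sessions follow a cumulative-normal psychometric detection rule with
per-assessor monotone profiles. The estimators never see the generating
rules: the panel simulator uses a psychometric function, while the
estimator applies only the 50%-detection rule.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem

from . import features as feat
from .panel import PanelSession
from .registry import CompoundRecord, canonicalize

#: Ring templates with an aromatic core — the default structural predicate
#: for a positive aroma contribution in the synthetic world. ``{0}``/``{1}``
#: are substituent attachment slots.
AROMATIC_TEMPLATES = (
    "{0}c1ccccc1",
    "{0}c1ccc2ccccc2c1",
    "{0}c1ccco1",
    "{0}c1cccs1",
    "{0}c1ccncc1",
    "{0}c1ccc2c(c1)OCO2",
    "{0}c1ccc2occc2c1",
    "{0}c1ccc2[nH]ccc2c1",
    "{0}c1cnc2ccccc2c1",
    "{0}c1ccc({1})cc1",
    "{0}c1cc({1})ccc1",
    "{0}c1ccc({1})o1",
    "{0}c1ccc({1})s1",
)

#: Non-aromatic templates; "{0}" alone is the acyclic pseudo-scaffold.
PLAIN_TEMPLATES = (
    "{0}",
    "{0}C1CCCCC1",
    "{0}C1CCCC1",
    "{0}C1CCOCC1",
    "{0}C1CCCCCC1",
    "{0}C1CCC2CCCCC2C1",
    "{0}C1CCOC1",
    "{0}C1CCC(=O)O1",
    "{0}C1CCC({1})CC1",
    "{0}C({1})CC",
)

#: Substituent fragments, each valid standalone, as a concatenation prefix,
#: and inside a SMILES branch.
SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
    "OC", "OCC", "OCCC", "OCCCC", "COC",
    "CC(=O)O", "CCC(=O)O", "CCCC(=O)O",
    "CC(C)", "CC(C)C", "CC(C)O", "C=C", "C=CC", "CCO", "CCCO", "CCOC",
)


@dataclass
class SynthSpec:
    """Generation parameters for a synthetic corpus.

    Defaults emulate the conditions of curated flavor-volatile corpora:
    a heavily positive-skewed contribution prevalence (≈0.86, matching
    26,934 positive vs 4,526 negative records), thresholds approximately
    normal on the -log10(mg/L) scale, and scaffold families with multiple
    members so scaffold-aware splitting is exercised.
    """

    n_molecules: int = 200
    aromatic_templates: tuple[str, ...] = AROMATIC_TEMPLATES
    plain_templates: tuple[str, ...] = PLAIN_TEMPLATES
    substituents: tuple[str, ...] = SUBSTITUENTS
    positive_fraction: float = 0.856
    flip_noise: float = 0.0
    # y = intercept + beta · [MW, logP, TPSA, MR] + N(0, sd); coefficients
    # scaled so y spans a few log10 units over the library, like real
    # threshold corpora.
    threshold_intercept: float = -1.0
    threshold_beta: tuple[float, float, float, float] = (0.02, -0.35, 0.015, 0.01)
    threshold_noise_sd: float = 0.3
    seed: int = 0


def is_positive_structure(smiles: str) -> bool:
    """Default structural predicate: molecule contains an aromatic ring."""
    mol = Chem.MolFromSmiles(smiles)
    return mol is not None and any(a.GetIsAromatic() for a in mol.GetAtoms())


@lru_cache(maxsize=8)
def _enumerate(templates: tuple[str, ...], substituents: tuple[str, ...]) -> tuple[str, ...]:
    out = []
    seen = set()
    for tmpl in templates:
        n_slots = tmpl.count("{")
        combos = (
            ((s,) for s in substituents)
            if n_slots == 1
            else ((a, b) for a in substituents for b in substituents)
        )
        for combo in combos:
            try:
                can = canonicalize(tmpl.format(*combo))
            except Exception:  # a template×substituent clash; skip it
                continue
            if can not in seen:
                seen.add(can)
                out.append(can)
    return tuple(out)


def gen_molecules(spec: SynthSpec) -> list[str]:
    """Sample *n_molecules* unique canonical SMILES from the template space.

    The aromatic (predicate-true) share of the sample targets
    ``positive_fraction``, so downstream label prevalence is controlled by
    construction. Raises when the enumerable space is too small.
    """
    pos_pool = _enumerate(spec.aromatic_templates, spec.substituents)
    neg_pool = _enumerate(spec.plain_templates, spec.substituents)
    n = spec.n_molecules
    if n > len(pos_pool) + len(neg_pool):
        raise ValueError(
            f"requested {n} molecules but the template space holds only "
            f"{len(pos_pool) + len(neg_pool)}; extend the libraries"
        )
    rng = np.random.default_rng([spec.seed, 0])
    n_pos = min(len(pos_pool), int(round(n * spec.positive_fraction)))
    n_neg = n - n_pos
    if n_neg > len(neg_pool):
        n_neg = len(neg_pool)
        n_pos = n - n_neg
    chosen = [pos_pool[i] for i in rng.choice(len(pos_pool), size=n_pos, replace=False)]
    chosen += [neg_pool[i] for i in rng.choice(len(neg_pool), size=n_neg, replace=False)]
    order = rng.permutation(len(chosen))
    return [chosen[i] for i in order]


def gen_labels(smiles_list, spec: SynthSpec) -> list[str]:
    """'positive'/'negative' labels from the structural predicate + flip noise."""
    rng = np.random.default_rng([spec.seed, 1])
    labels = []
    for s in smiles_list:
        lab = is_positive_structure(s)
        if spec.flip_noise > 0 and rng.random() < spec.flip_noise:
            lab = not lab
        labels.append("positive" if lab else "negative")
    return labels


def gen_thresholds(smiles_list, spec: SynthSpec) -> np.ndarray:
    """y = -log10(threshold mg/L) values from the linear physchem rule."""
    rng = np.random.default_rng([spec.seed, 2])
    beta = np.asarray(spec.threshold_beta, dtype=np.float64)
    pc = np.stack([feat.physchem(s) for s in smiles_list])
    y = spec.threshold_intercept + pc @ beta
    if spec.threshold_noise_sd > 0:
        y = y + rng.normal(0.0, spec.threshold_noise_sd, size=y.shape)
    return y


_POSITIVE_DESCRIPTORS = (("fruity", "floral"), ("sweet", "rose"), ("apple", "honey"))
_NEGATIVE_DESCRIPTORS = (("musty", "grassy"), ("rancid", "solvent"), ("sweaty", "plastic"))


def gen_corpus(spec: SynthSpec) -> list[CompoundRecord]:
    """Full synthetic compound records (descriptors + threshold observations)
    that pass the registry and curation stages unmodified.

    Descriptors encode the generated label through the default curation
    rules; thresholds are emitted in mg/L so curation's -log10 transform
    recovers the generated y exactly.
    """
    smiles = gen_molecules(spec)
    labels = gen_labels(smiles, spec)
    ys = gen_thresholds(smiles, spec)
    rng = np.random.default_rng([spec.seed, 3])
    records = []
    for s, lab, y in zip(smiles, labels, ys):
        pool = _POSITIVE_DESCRIPTORS if lab == "positive" else _NEGATIVE_DESCRIPTORS
        records.append(
            CompoundRecord(
                smiles_raw=s,
                smiles_canonical=s,
                descriptors_raw=list(pool[rng.integers(len(pool))]),
                threshold_obs=[float(10.0 ** (-y))],
            )
        )
    return records


def gen_panel(
    true_threshold: float,
    slope: float = 2.0,
    n_panelists: int = 20,
    concentrations=None,
    seed: int | None = None,
) -> PanelSession:
    """Simulate an ascending-series session with a psychometric detection rule.

    Assessor *i* gets a log10-sensitivity s_i ~ N(log10 t, 1/slope) and
    detects concentration c iff log10 c ≥ s_i, so P(detect) =
    Φ(slope · (log10 c − log10 t)) and every profile is monotone by
    construction. slope → ∞ makes detection a step at the true threshold.
    Default concentrations: blank + 10-fold series bracketing the truth.
    """
    if true_threshold <= 0:
        raise ValueError("true_threshold must be > 0")
    if concentrations is None:
        base = math.floor(math.log10(true_threshold))
        concentrations = [0.0] + [10.0 ** p for p in range(base - 2, base + 4)]
    concentrations = np.asarray(concentrations, dtype=np.float64)
    if np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentrations must be ascending")
    rng = np.random.default_rng(seed)
    sens = math.log10(true_threshold) + rng.normal(0.0, 1.0 / slope, size=n_panelists)
    det = np.zeros((n_panelists, concentrations.size), dtype=np.int64)
    nz = concentrations > 0
    with np.errstate(divide="ignore"):
        logc = np.where(nz, np.log10(np.where(nz, concentrations, 1.0)), -np.inf)
    det[:, :] = (logc[None, :] >= sens[:, None]) & nz[None, :]
    return PanelSession(concentrations=concentrations, detection=det, compound="synthetic")
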