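"""Murcko scaffold-aware train/validation splitting.

Compounds sharing a Bemis–Murcko framework (ring systems plus linkers,
terminal side chains stripped) are never divided across the split, so
validation performance reflects generalization to unseen chemotypes rather
than memorization of close analogues. Acyclic molecules — common among
flavor volatiles (esters, aldehydes, alcohols) — all collapse to the empty
scaffold "" and are treated as one indivisible group; this coarseness is
deliberate and documented.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold

from .registry import SmilesParseError


def murcko(smiles: str) -> str:
    """Canonical SMILES of the Bemis–Murcko scaffold; "" for acyclic molecules."""
    try:
        return MurckoScaffold.MurckoScaffoldSmiles(smiles)
    except Exception as exc:  # RDKit raises bare ValueError on parse failure
        raise SmilesParseError(smiles) from exc


@dataclass
class SplitAssignment:
    """Scaffold-keyed membership for every compound in a split."""

    smiles: list[str]
    scaffold_keys: list[str]
    membership: list[str]  # "train" | "validation"
    target_fraction: float
    seed: int | None = None

    @property
    def train_smiles(self) -> list[str]:
        return [s for s, m in zip(self.smiles, self.membership) if m == "train"]

    @property
    def validation_smiles(self) -> list[str]:
        return [s for s, m in zip(self.smiles, self.membership) if m == "validation"]

    @property
    def achieved_fraction(self) -> float:
        return len(self.validation_smiles) / len(self.smiles)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["smiles", "scaffold_key", "membership"])
            for row in zip(self.smiles, self.scaffold_keys, self.membership):
                w.writerow(row)


def greedy_split(
    smiles_list: list[str],
    target_fraction: float = 0.2,
    seed: int | None = None,
    shuffle_groups: bool = False,
) -> SplitAssignment:
    """Greedy scaffold split at a target validation fraction.

    Groups compounds by scaffold key, orders groups by (size descending,
    key ascending), and fills the training set group by group until the next
    group would push it past (1 - f)·N; every remaining group goes to
    validation. Large scaffold families therefore train, and rare scaffolds
    validate — the harder, more honest generalization test. The procedure is
    deterministic and independent of input row order; *seed* only matters in
    the optional shuffled-greedy mode (*shuffle_groups*), which randomizes
    group order instead of sorting by size.

    Raises
    ------
    ValueError
        If fewer than two scaffold groups exist (split impossible) or the
        fraction is outside (0, 1).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0,1), got {target_fraction}")
    keys = {s: murcko(s) for s in smiles_list}
    groups: dict[str, list[str]] = {}
    for s in sorted(set(smiles_list)):
        groups.setdefault(keys[s], []).append(s)
    if len(groups) < 2:
        raise ValueError(
            "split impossible: fewer than 2 scaffold groups "
            f"(all {len(smiles_list)} compounds share one scaffold)"
        )
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    if shuffle_groups:
        rng = np.random.default_rng(seed)
        ordered = [ordered[i] for i in rng.permutation(len(ordered))]
    n_total = sum(len(v) for v in groups.values())
    train_cap = (1.0 - target_fraction) * n_total
    membership: dict[str, str] = {}
    n_train = 0
    filling = True
    for key, members in ordered:
        if filling and n_train + len(members) <= train_cap:
            membership[key] = "train"
            n_train += len(members)
        else:
            filling = False  # first overflow closes training
            membership[key] = "validation"
    if n_train == 0 or n_train == n_total:
        raise ValueError("degenerate split: one side is empty at this fraction")
    smiles_sorted = [s for _, members in ordered for s in members]
    return SplitAssignment(
        smiles=smiles_sorted,
        scaffold_keys=[keys[s] for s in smiles_sorted],
        membership=[membership[keys[s]] for s in smiles_sorted],
        target_fraction=target_fraction,
        seed=seed,
    )
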