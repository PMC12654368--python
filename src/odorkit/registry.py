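"""Compound ingestion: SMILES canonicalization, name resolution, deduplication.

The registry turns heterogeneous compound tables (names and/or SMILES, raw
odor descriptors, literature threshold observations) into one clean record
per molecule, keyed by canonical SMILES. Name resolution is purely local:
a small built-in lookup table covers common flavor volatiles and users can
supply their own; no network access ever happens here.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about every unparseable SMILES; we report rejects ourselves.
RDLogger.DisableLog("rdApp.error")

#: Sentinel returned by :func:`resolve_name` when a name has no table entry.
UNRESOLVED = "__unresolved__"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the offender."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass
class CompoundRecord:
    """One volatile compound with its sensory annotations.

    Thresholds are in mg/L (water matrix) and must be positive; descriptor
    strings are kept raw here and interpreted by the curation stage.
    """

    smiles_raw: str
    smiles_canonical: str = ""
    name: str | None = None
    aliases: list[str] = field(default_factory=list)
    descriptors_raw: list[str] = field(default_factory=list)
    threshold_obs: list[float] = field(default_factory=list)
    concentration: float | None = None


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*.

    Stereochemistry flags are retained as written. Idempotent:
    ``canonicalize(canonicalize(s)) == canonicalize(s)``.

    Raises
    ------
    SmilesParseError
        If RDKit cannot parse the input.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


class NameLookup:
    """Case-insensitive compound-name → SMILES table, loaded from CSV.

    Every mapped SMILES is validated at load time; lookup is pure.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        for name, smi in (mapping or {}).items():
            self._map[name.strip().lower()] = canonicalize(smi)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NameLookup":
        mapping = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                mapping[row["name"]] = row["smiles"]
        return cls(mapping)

    @classmethod
    def builtin(cls) -> "NameLookup":
        """The lookup table shipped with the package (common flavor volatiles)."""
        ref = resources.files("odorkit.data").joinpath("name_lookup.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._map

    def get(self, name: str) -> str | None:
        return self._map.get(name.strip().lower())


def resolve_name(name: str, lookup: NameLookup) -> str:
    """Resolve a compound name to SMILES via *lookup*.

    Matching is exact after lowercasing and trimming. A miss returns the
    :data:`UNRESOLVED` marker — misses are data, not faults — and is logged.
    """
    smi = lookup.get(name)
    if smi is None:
        logger.info("name not resolved: %r", name)
        return UNRESOLVED
    return smi


def dedupe(
    records: list[CompoundRecord], threshold_policy: str = "median"
) -> list[CompoundRecord]:
    """Merge records sharing a canonical SMILES into one record each.

    Descriptor lists are unioned (order-stable, first occurrence wins),
    threshold observations pooled (collapse happens later, at curation, by
    *threshold_policy*), and conflicting names resolved to the
    lexicographically first with the rest kept as aliases. Output is sorted
    by canonical SMILES for determinism.
    """
    if threshold_policy not in ("median", "mean"):
        raise ValueError(f"unknown threshold policy: {threshold_policy!r}")
    merged: dict[str, CompoundRecord] = {}
    for rec in records:
        if not rec.smiles_canonical:
            raise ValueError(f"record not canonicalized: {rec.smiles_raw!r}")
        key = rec.smiles_canonical
        if key not in merged:
            merged[key] = CompoundRecord(
                smiles_raw=rec.smiles_raw,
                smiles_canonical=key,
                name=rec.name,
                aliases=list(rec.aliases),
                descriptors_raw=list(rec.descriptors_raw),
                threshold_obs=list(rec.threshold_obs),
                concentration=rec.concentration,
            )
            continue
        tgt = merged[key]
        for d in rec.descriptors_raw:
            if d not in tgt.descriptors_raw:
                tgt.descriptors_raw.append(d)
        tgt.threshold_obs.extend(rec.threshold_obs)
        names = sorted(
            {n for n in [tgt.name, rec.name, *tgt.aliases, *rec.aliases] if n}
        )
        tgt.name = names[0] if names else None
        tgt.aliases = names[1:]
        if tgt.concentration is None:
            tgt.concentration = rec.concentration
    return [merged[k] for k in sorted(merged)]


def load_compound_table(
    path: str | Path,
    lookup: NameLookup | None = None,
    threshold_policy: str = "median",
) -> tuple[list[CompoundRecord], list[dict]]:
    """Read a delimited compound table into deduplicated records.

    Expected columns: ``name``, ``smiles`` (either may be empty, not both),
    ``descriptors`` (semicolon-separated), ``threshold_mg_L``
    (semicolon-separated numerics), ``concentration_mg_L``. Delimiter is
    sniffed between comma and tab.

    Returns ``(records, exclusions)`` where *exclusions* is a manifest of
    dropped rows (unresolvable names, unparseable SMILES) suitable for JSON
    serialization. Dropping is deliberate: curation removes entries with
    missing structures rather than failing the whole table.
    """
    lookup = lookup or NameLookup.builtin()
    records: list[CompoundRecord] = []
    exclusions: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if sample.count("\t") > sample.count(",") else ","
        for i, row in enumerate(csv.DictReader(fh, delimiter=delim)):
            name = (row.get("name") or "").strip() or None
            smi = (row.get("smiles") or "").strip()
            if not smi and name:
                smi = resolve_name(name, lookup)
                if smi == UNRESOLVED:
                    exclusions.append(
                        {"row": i, "name": name, "reason": "name_unresolved"}
                    )
                    continue
            if not smi:
                exclusions.append({"row": i, "name": name, "reason": "no_structure"})
                continue
            try:
                canonical = canonicalize(smi)
            except SmilesParseError:
                exclusions.append(
                    {"row": i, "name": name, "smiles": smi, "reason": "smiles_unparseable"}
                )
                continue
            desc = [d.strip() for d in (row.get("descriptors") or "").split(";") if d.strip()]
            thr = []
            for tok in (row.get("threshold_mg_L") or "").split(";"):
                tok = tok.strip()
                if tok:
                    try:
                        thr.append(float(tok))
                    except ValueError:
                        exclusions.append(
                            {"row": i, "name": name, "value": tok, "reason": "threshold_unparseable"}
                        )
            conc_tok = (row.get("concentration_mg_L") or "").strip()
            conc = float(conc_tok) if conc_tok else None
            records.append(
                CompoundRecord(
                    smiles_raw=smi,
                    smiles_canonical=canonical,
                    name=name,
                    descriptors_raw=desc,
                    threshold_obs=thr,
                    concentration=conc,
                )
            )
    return dedupe(records, threshold_policy), exclusions


def write_normalized(
    records: list[CompoundRecord],
    exclusions: list[dict],
    out_csv: str | Path,
    out_manifest: str | Path | None = None,
) -> None:
    """Write the normalized table and the JSON exclusion manifest."""
    with open(out_csv, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["name", "smiles", "descriptors", "threshold_mg_L", "concentration_mg_L"]
        )
        for r in records:
            w.writerow(
                [
                    r.name or "",
                    r.smiles_canonical,
                    ";".join(r.descriptors_raw),
                    ";".join(repr(t) for t in r.threshold_obs),
                    "" if r.concentration is None else repr(r.concentration),
                ]
            )
    if out_manifest is not None:
        with open(out_manifest, "w", encoding="utf-8") as fh:
            json.dump({"excluded": exclusions, "n_excluded": len(exclusions)}, fh, indent=2)
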