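"""Resolve raw per-replicate protein-group quantifications into a
condition-level absolute abundance table in model units.

Protein groups quantified through shared (non-proteotypic) peptides arrive as
ambiguous entries whose id set has more than one member; those are resolved by
iterative subtraction of unambiguous quantifications. Surviving values are
median-aggregated over replicates and converted from amol/cell to mmol/gDW.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model_io import ConditionSpec

#: Literature dry weight of a mixotrophically grown reference cell, in pg.
DRY_WEIGHT_PG = 48000.0


@dataclass(frozen=True)
class AbundanceEntry:
    proteins: frozenset[str]
    value: float  # amol/cell

    @property
    def ambiguous(self) -> bool:
        return len(self.proteins) > 1


@dataclass
class RawAbundanceSample:
    condition_id: str
    replicate: int
    entries: list[AbundanceEntry]

    def total_mass(self) -> float:
        return sum(e.value for e in self.entries)


def resolve_ambiguous_entries(sample: RawAbundanceSample) -> RawAbundanceSample:
    """Iteratively resolve shared-peptide entries against unambiguous ones.

    While an ambiguous entry shares a protein with an unambiguous entry, the
    unambiguous concentration is subtracted and the protein id removed; entries
    that go negative are dropped. Ambiguous entries reduced to a single id
    become unambiguous and participate in further rounds. Whatever remains
    ambiguous at the fixed point is discarded. Ambiguous entries are processed
    in ascending set size, ties broken lexicographically, so the output is
    deterministic.
    """
    unambig: dict[str, float] = {}
    ambiguous: list[tuple[set[str], float]] = []
    for e in sample.entries:
        if e.value < 0:
            raise ValueError("negative concentration in raw sample")
        if e.ambiguous:
            ambiguous.append((set(e.proteins), e.value))
        else:
            (pid,) = e.proteins
            unambig[pid] = unambig.get(pid, 0.0) + e.value

    changed = True
    while changed:
        changed = False
        ambiguous.sort(key=lambda t: (len(t[0]), tuple(sorted(t[0]))))
        remaining: list[tuple[set[str], float]] = []
        for proteins, value in ambiguous:
            shared = proteins & unambig.keys()
            if shared:
                changed = True
                value -= sum(unambig[p] for p in shared)
                proteins -= shared
            if value < 0:
                changed = True
                continue  # negative after subtraction: entry removed
            if len(proteins) == 1:
                changed = True
                (pid,) = proteins
                unambig[pid] = unambig.get(pid, 0.0) + value
            elif len(proteins) == 0:
                changed = True
            else:
                remaining.append((proteins, value))
        ambiguous = remaining

    entries = [
        AbundanceEntry(frozenset([pid]), value)
        for pid, value in sorted(unambig.items())
    ]
    return RawAbundanceSample(
        condition_id=sample.condition_id,
        replicate=sample.replicate,
        entries=entries,
    )


def aggregate_replicates(
    samples: list[RawAbundanceSample], min_replicates: int = 2
) -> dict[str, float]:
    """Median abundance per protein over replicates of one condition.

    Proteins quantified in fewer than ``min_replicates`` replicates are
    dropped (the study used 2 of 3).
    """
    if not samples:
        raise ValueError("no replicate samples to aggregate")
    conditions = {s.condition_id for s in samples}
    if len(conditions) != 1:
        raise ValueError(f"samples span multiple conditions: {sorted(conditions)}")
    values: dict[str, list[float]] = {}
    for s in samples:
        for e in s.entries:
            if e.ambiguous:
                raise ValueError("aggregate_replicates expects resolved samples")
            (pid,) = e.proteins
            values.setdefault(pid, []).append(e.value)
    return {
        pid: statistics.median(v)
        for pid, v in sorted(values.items())
        if len(v) >= min_replicates
    }


def convert_abundance_units(
    abundance_amol_per_cell: float,
    condition: ConditionSpec | float,
    dry_weight_pg: float = DRY_WEIGHT_PG,
) -> float:
    """amol/cell -> mmol/gDW using dry weight scaled by relative cell volume.

    Dry weight per cell is ``dry_weight_pg * relative_cell_volume`` pg,
    assuming constant dry weight density across conditions.
    """
    if abundance_amol_per_cell < 0:
        raise ValueError("abundance must be >= 0")
    rel_volume = (
        condition.relative_cell_volume
        if isinstance(condition, ConditionSpec)
        else float(condition)
    )
    if not rel_volume > 0:
        raise ValueError("relative cell volume must be > 0")
    grams_per_cell = dry_weight_pg * rel_volume * 1e-12
    mmol_per_cell = abundance_amol_per_cell * 1e-18 * 1e3
    return mmol_per_cell / grams_per_cell


def invert_abundance_units(
    abundance_mmol_per_gdw: float,
    condition: ConditionSpec | float,
    dry_weight_pg: float = DRY_WEIGHT_PG,
) -> float:
    """Inverse of :func:`convert_abundance_units` (mmol/gDW -> amol/cell)."""
    rel_volume = (
        condition.relative_cell_volume
        if isinstance(condition, ConditionSpec)
        else float(condition)
    )
    grams_per_cell = dry_weight_pg * rel_volume * 1e-12
    return abundance_mmol_per_gdw * grams_per_cell / 1e-15


@dataclass
class AbundanceTable:
    """Replicate-aggregated absolute abundances per (protein, condition)."""

    amol_per_cell: dict[tuple[str, str], float] = field(default_factory=dict)
    mmol_per_gdw: dict[tuple[str, str], float] = field(default_factory=dict)
    n_replicates_used: dict[str, int] = field(default_factory=dict)
    non_model_proteins: set[str] = field(default_factory=set)

    def proteins(self) -> list[str]:
        return sorted({p for p, _ in self.amol_per_cell})

    def conditions(self) -> list[str]:
        return sorted({c for _, c in self.amol_per_cell})

    def amol(self, protein: str, condition: str) -> float | None:
        return self.amol_per_cell.get((protein, condition))

    def mmol(self, protein: str, condition: str) -> float | None:
        return self.mmol_per_gdw.get((protein, condition))

    def measured_proteins(self, condition: str) -> set[str]:
        return {p for (p, c), v in self.mmol_per_gdw.items() if c == condition and v > 0}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": p,
                "condition": c,
                "amol_per_cell": v,
                "mmol_per_gDW": self.mmol_per_gdw[(p, c)],
            }
            for (p, c), v in sorted(self.amol_per_cell.items())
        ]
        return pd.DataFrame(
            rows, columns=["protein_id", "condition", "amol_per_cell", "mmol_per_gDW"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_abundance_table(
    samples: list[RawAbundanceSample],
    conditions: list[ConditionSpec],
    model_genes: set[str] | None = None,
    min_replicates: int = 2,
) -> AbundanceTable:
    """Resolve, aggregate, and unit-convert all replicate samples.

    Proteins absent from ``model_genes`` are retained but flagged non-model
    (they are still needed to compute the enzyme mass fraction f).
    """
    cond_by_id = {c.condition_id: c for c in conditions}
    by_condition: dict[str, list[RawAbundanceSample]] = {}
    for s in samples:
        if s.condition_id not in cond_by_id:
            raise KeyError(f"sample condition '{s.condition_id}' not in metadata")
        by_condition.setdefault(s.condition_id, []).append(s)

    table = AbundanceTable()
    for cond_id in sorted(by_condition):
        cond = cond_by_id[cond_id]
        resolved = [resolve_ambiguous_entries(s) for s in by_condition[cond_id]]
        aggregated = aggregate_replicates(resolved, min_replicates=min_replicates)
        table.n_replicates_used[cond_id] = len(resolved)
        for pid, amol in aggregated.items():
            table.amol_per_cell[(pid, cond_id)] = amol
            table.mmol_per_gdw[(pid, cond_id)] = convert_abundance_units(amol, cond)
            if model_genes is not None and pid not in model_genes:
                table.non_model_proteins.add(pid)
    return table


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_replicate_tsv(
    path: str | Path, condition_id: str, replicate: int
) -> RawAbundanceSample:
    """Read one replicate file: protein_ids (semicolon-joined) <TAB> amol_per_cell."""
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = [
        AbundanceEntry(
            frozenset(str(row["protein_ids"]).split(";")),
            float(row["amol_per_cell"]),
        )
        for _, row in df.iterrows()
    ]
    return RawAbundanceSample(condition_id=condition_id, replicate=replicate, entries=entries)


def write_replicate_tsv(sample: RawAbundanceSample, path: str | Path) -> None:
    rows = [
        {"protein_ids": ";".join(sorted(e.proteins)), "amol_per_cell": e.value}
        for e in sample.entries
    ]
    pd.DataFrame(rows, columns=["protein_ids", "amol_per_cell"]).to_csv(
        path, sep="\t", index=False
    )
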