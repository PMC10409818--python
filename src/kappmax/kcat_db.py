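"""Literature turnover-number assignment by a taxon/substrate matching cascade.

Entries come from a local TSV snapshot (never a live query). For a reaction,
candidates with an exactly matching EC number are filtered through four tiers
of decreasing stringency -- organism taxon & substrate, organism taxon, wider
taxon & substrate, wider taxon -- and the maximum value at the first nonempty
tier is assigned.
"""
from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

_FULL_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


@dataclass(frozen=True)
class KcatEntry:
    ec_number: str
    organism: str
    lineage_tags: frozenset[str]
    substrate: str
    value: float  # 1/s
    from_specific_activity: bool = False

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError("kcat value must be > 0")
        if not _FULL_EC_RE.match(self.ec_number):
            raise ValueError(f"entry EC number '{self.ec_number}' is not fully specified")


@dataclass(frozen=True)
class KcatMatch:
    reaction_id: str
    value: float
    tier: int
    n_candidates: int


def _norm(s: str) -> str:
    return " ".join(s.split()).lower()


def match_kcat(
    reaction_id: str,
    ec_numbers: list[str],
    substrates: list[str],
    kcat_entries: list[KcatEntry],
    organism: str,
    taxon: str,
) -> KcatMatch | None:
    """Cascade match; returns the max value at the first nonempty tier, or None.

    Query EC numbers must be fully specified (wildcards rejected); substrate
    comparison is case-insensitive exact match after whitespace normalization.
    """
    if not ec_numbers:
        return None
    for ec in ec_numbers:
        if not _FULL_EC_RE.match(ec):
            raise ValueError(f"partial/wildcard EC query '{ec}' is not supported")
    ec_set = set(ec_numbers)
    candidates = [e for e in kcat_entries if e.ec_number in ec_set]
    if not candidates:
        return None
    subs = {_norm(s) for s in substrates}
    org = _norm(organism)
    tax = _norm(taxon)

    def in_organism(e: KcatEntry) -> bool:
        tags = {_norm(t) for t in e.lineage_tags}
        return _norm(e.organism) == org or org in tags

    def in_taxon(e: KcatEntry) -> bool:
        tags = {_norm(t) for t in e.lineage_tags}
        return tax in tags or _norm(e.organism) == tax

    def substrate_ok(e: KcatEntry) -> bool:
        return _norm(e.substrate) in subs

    tiers = [
        lambda e: in_organism(e) and substrate_ok(e),
        in_organism,
        lambda e: in_taxon(e) and substrate_ok(e),
        in_taxon,
    ]
    for tier_idx, predicate in enumerate(tiers, start=1):
        hits = [e for e in candidates if predicate(e)]
        if hits:
            return KcatMatch(
                reaction_id=reaction_id,
                value=max(e.value for e in hits),
                tier=tier_idx,
                n_candidates=len(hits),
            )
    return None


def match_network_kcats(
    network, kcat_entries: list[KcatEntry], organism: str, taxon: str
) -> dict[str, KcatMatch]:
    """Match every annotated reaction of a network; unannotated ones skipped."""
    out = {}
    for r in network.reactions:
        if not r.ec_numbers:
            continue
        substrates = [m for m, coef in r.stoichiometry.items() if coef < 0]
        m = match_kcat(r.id, r.ec_numbers, substrates, kcat_entries, organism, taxon)
        if m is not None:
            out[r.id] = m
    return out


# ---------------------------------------------------------------------------
# in vivo vs in vitro comparison
# ---------------------------------------------------------------------------

@dataclass
class KappKcatComparison:
    lfd: dict[str, float]
    median_lfd: float
    spearman_rho: float
    p_value: float
    n: int


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value by full enumeration (small n only)."""
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    denom = math.sqrt(float((xc**2).sum()) * float(((y_ranks - y_ranks.mean()) ** 2).sum()))
    count = 0
    total = 0
    for perm in itertools.permutations(y_ranks):
        yp = np.asarray(perm, dtype=float)
        rho = float((xc * (yp - yp.mean())).sum()) / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def compare_kapp_kcat(
    kappmax: dict[str, float],
    kcat: dict[str, float],
    exact_max_n: int = 8,
) -> KappKcatComparison:
    """Per-reaction log10-fold differences and rank correlation of log values.

    LFD = log10(kapp_max) - log10(kcat). The Spearman p-value is computed by
    exhaustive permutation for n <= ``exact_max_n`` and by the large-sample
    approximation otherwise.
    """
    shared = sorted(set(kappmax) & set(kcat))
    if not shared:
        raise ValueError("no shared reactions between kapp_max and kcat tables")
    lfd = {r: math.log10(kappmax[r]) - math.log10(kcat[r]) for r in shared}
    x = np.log10([kappmax[r] for r in shared])
    y = np.log10([kcat[r] for r in shared])
    if len(shared) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(x, y)
        rho = float(rho)
        if len(shared) <= exact_max_n:
            xr = stats.rankdata(x)
            yr = stats.rankdata(y)
            p = _exact_spearman_p(xr, yr, rho)
        else:
            p = float(p)
    return KappKcatComparison(
        lfd=lfd,
        median_lfd=float(np.median(list(lfd.values()))),
        spearman_rho=rho,
        p_value=p,
        n=len(shared),
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_kcat_table(path: str | Path) -> list[KcatEntry]:
    """Columns: ec_number, organism, lineage_tags (semicolon-joined),
    substrate, kcat_per_s, and an optional source_flag ('SA' marks values
    derived from specific activity)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for _, row in df.iterrows():
        tags = str(row.get("lineage_tags", "") or "")
        entries.append(
            KcatEntry(
                ec_number=str(row["ec_number"]),
                organism=str(row["organism"]),
                lineage_tags=frozenset(t for t in tags.split(";") if t),
                substrate=str(row.get("substrate", "") or ""),
                value=float(row["kcat_per_s"]),
                from_specific_activity=str(row.get("source_flag", "")).upper() == "SA",
            )
        )
    return entries


def write_kcat_table(entries: list[KcatEntry], path: str | Path) -> None:
    rows = [
        {
            "ec_number": e.ec_number,
            "organism": e.organism,
            "lineage_tags": ";".join(sorted(e.lineage_tags)),
            "substrate": e.substrate,
            "kcat_per_s": e.value,
            "source_flag": "SA" if e.from_specific_activity else "",
        }
        for e in entries
    ]
    pd.DataFrame(
        rows,
        columns=["ec_number", "organism", "lineage_tags", "substrate", "kcat_per_s", "source_flag"],
    ).to_csv(path, sep="\t", index=False)


def write_match_table(matches: dict[str, KcatMatch], path: str | Path) -> None:
    rows = [
        {
            "reaction_id": m.reaction_id,
            "kcat_per_s": m.value,
            "tier": m.tier,
            "n_candidates": m.n_candidates,
        }
        for m in matches.values()
    ]
    pd.DataFrame(
        rows, columns=["reaction_id", "kcat_per_s", "tier", "n_candidates"]
    ).to_csv(path, sep="\t", index=False)
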