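"""Condition-specific apparent catalytic rates and their per-reaction maxima.

Single-enzyme reactions use the flux/abundance ratio directly. Reactions with
several expressed isoenzymes are decomposed by bounded least squares (or an
L1 variant) over a designated set of standard conditions, assuming each
isoenzyme keeps one rate across conditions; per-condition effective rates are
abundance-weighted averages of the fitted rates. Internally rates are 1/h to
match the fit; reported tables are 1/s.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import linprog, lsq_linear

from .errors import SolverError
from .model_io import IsoenzymeSet
from .nidle import enzyme_key

#: Default lower bound on fitted isoenzyme rates, in 1/h (= 1e-10 1/s).
DEFAULT_EPSILON_PER_H = 1e-10 * 3600.0
#: Ridge weight selecting the minimum-norm optimum in degenerate systems.
RIDGE = 1e-12
SECONDS_PER_HOUR = 3600.0


def kapp_single(v: float, E: float) -> float | None:
    """Apparent catalytic rate (1/s) of a single-enzyme reaction.

    ``v`` in mmol/gDW/h, ``E`` in mmol/gDW. Returns None (no estimate) when
    either quantity is non-positive.
    """
    if v <= 0 or E <= 0:
        return None
    return (v / E) / SECONDS_PER_HOUR


@dataclass
class IsoenzymeFit:
    reaction_id: str
    conditions: list[str]
    isoenzymes: list[str]
    k_per_h: np.ndarray          # fitted rates, 1/h
    residuals: np.ndarray        # delta_j per condition, mmol/gDW/h
    epsilon_per_h: float
    norm: str

    @property
    def at_lower_bound(self) -> np.ndarray:
        return self.k_per_h <= self.epsilon_per_h * (1.0 + 1e-9)

    @property
    def sum_squared_residuals(self) -> float:
        return float(np.sum(self.residuals**2))


def fit_isoenzyme_kapp(
    E_matrix: np.ndarray,
    v: np.ndarray,
    epsilon_per_h: float = DEFAULT_EPSILON_PER_H,
    norm: str = "l2",
    reaction_id: str = "",
    conditions: list[str] | None = None,
    isoenzymes: list[str] | None = None,
) -> IsoenzymeFit:
    """Decompose fluxes into per-isoenzyme rates with a rate lower bound.

    Solves min ||delta||_2^2 (or ||delta||_1) subject to
    E_matrix @ k + delta = v and k >= epsilon. ``E_matrix`` is
    conditions x isoenzymes in mmol/gDW; ``v`` per-condition flux in
    mmol/gDW/h; the fitted ``k`` are in 1/h. A tiny ridge term makes the L2
    optimum unique on under-determined systems.
    """
    E = np.atleast_2d(np.asarray(E_matrix, dtype=float))
    v = np.asarray(v, dtype=float).ravel()
    if E.size == 0 or v.size == 0:
        raise ValueError("empty isoenzyme system")
    if E.shape[0] != v.shape[0]:
        raise ValueError("E_matrix rows must match v length")
    if not (E >= 0).all():
        raise ValueError("abundances must be non-negative")
    if not np.any(E.sum(axis=1) > 0):
        raise ValueError("each system needs at least one positive abundance row")
    n_cond, n_iso = E.shape

    if norm == "l2":
        # tie-break ridge scaled by column norms so the penalty on E_i * k_i is
        # ~RIDGE relative to the residual scale regardless of units
        col_scale = np.linalg.norm(E, axis=0)
        col_scale[col_scale == 0] = 1.0
        A = np.vstack([E, np.sqrt(RIDGE) * np.diag(col_scale)])
        b = np.concatenate([v, np.zeros(n_iso)])
        res = lsq_linear(A, b, bounds=(epsilon_per_h, np.inf), method="bvls")
        if res.status <= 0:
            raise SolverError(f"bounded least squares failed: {res.message}")
        k = res.x
    elif norm == "l1":
        # min sum(t) s.t. -t <= v - E k <= t, k >= eps; vars = [k, t]
        n = n_iso + n_cond
        c = np.concatenate([np.zeros(n_iso), np.ones(n_cond)])
        A_ub = np.vstack(
            [
                np.hstack([E, -np.eye(n_cond)]),   # E k - t <= v
                np.hstack([-E, -np.eye(n_cond)]),  # -E k - t <= -v
            ]
        )
        b_ub = np.concatenate([v, -v])
        bounds = [(epsilon_per_h, None)] * n_iso + [(0, None)] * n_cond
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if not res.success:
            raise SolverError(f"L1 fit failed: {res.message}")
        k = res.x[:n_iso]
    else:
        raise ValueError("norm must be 'l2' or 'l1'")

    k = np.maximum(k, epsilon_per_h)
    residuals = v - E @ k
    return IsoenzymeFit(
        reaction_id=reaction_id,
        conditions=list(conditions) if conditions is not None else [str(j) for j in range(n_cond)],
        isoenzymes=list(isoenzymes) if isoenzymes is not None else [str(i) for i in range(n_iso)],
        k_per_h=k,
        residuals=residuals,
        epsilon_per_h=epsilon_per_h,
        norm=norm,
    )


def effective_kapp(E_row: np.ndarray, k: np.ndarray) -> float | None:
    """Abundance-weighted average rate: sum(E_i k_i) / sum(E_i) (same units as k)."""
    E_row = np.asarray(E_row, dtype=float)
    k = np.asarray(k, dtype=float)
    total = E_row.sum()
    if total <= 0:
        return None
    return float((E_row * k).sum() / total)


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappEntry:
    reaction_id: str
    condition_id: str
    kapp_per_s: float
    source: str  # single_enzyme | isoenzyme_qp | isoenzyme_l1
    at_lower_bound: bool = False


@dataclass
class KappTable:
    entries: list[KappEntry] = field(default_factory=list)

    def reactions(self) -> list[str]:
        return sorted({e.reaction_id for e in self.entries})

    def conditions(self) -> list[str]:
        return sorted({e.condition_id for e in self.entries})

    def get(self, reaction_id: str, condition_id: str) -> KappEntry | None:
        for e in self.entries:
            if e.reaction_id == reaction_id and e.condition_id == condition_id:
                return e
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction_id": e.reaction_id,
                    "condition": e.condition_id,
                    "kapp_per_s": e.kapp_per_s,
                    "source": e.source,
                }
                for e in self.entries
            ],
            columns=["reaction_id", "condition", "kapp_per_s", "source"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _abundance_lookup(abundance):
    """Accept an AbundanceTable or a plain {(protein, condition): mmol} mapping."""
    if hasattr(abundance, "mmol"):
        return lambda p, c: abundance.mmol(p, c)
    return lambda p, c: abundance.get((p, c))


def build_kapp_table(
    fluxes: dict[str, dict[str, float]],
    abundance,
    iso_sets: dict[str, IsoenzymeSet],
    std_conditions: list[str],
    epsilon_per_h: float = DEFAULT_EPSILON_PER_H,
    min_flux: float = 1e-9,
    norm: str = "l2",
    qp_outside_std: bool = True,
) -> KappTable:
    """Assemble the per-(reaction, condition) apparent-rate table.

    ``fluxes`` maps condition -> reaction -> flux (mmol/gDW/h) on the
    irreversible network; ``iso_sets`` is keyed by the same reaction ids.
    Reactions whose GPR needs a multi-subunit complex are excluded. Conditions
    where exactly one isoenzyme is expressed use the direct ratio; conditions
    with >= 2 expressed isoenzymes use the decomposition fitted on
    ``std_conditions`` (applied outside the standard set too unless
    ``qp_outside_std`` is False). Entries equal to the rate lower bound are
    dropped.
    """
    lookup = _abundance_lookup(abundance)
    conditions = sorted(fluxes)
    missing_std = [c for c in std_conditions if c not in conditions]
    if missing_std:
        raise ValueError(f"standard conditions without flux data: {missing_std}")
    source_multi = "isoenzyme_qp" if norm == "l2" else "isoenzyme_l1"

    entries: list[KappEntry] = []
    for rid in sorted(iso_sets):
        iso = iso_sets[rid]
        if not iso.complexes or iso.is_complex_reaction():
            continue
        genes = sorted(c for cplx in iso.complexes for c in cplx)

        def expressed(cond: str) -> list[str]:
            return [g for g in genes if (lookup(g, cond) or 0.0) > 0]

        def flux_of(cond: str) -> float:
            return fluxes[cond].get(rid, 0.0)

        multi_conditions = [
            c
            for c in conditions
            if flux_of(c) > min_flux and len(expressed(c)) >= 2
        ]

        fit = None
        fit_genes: list[str] = []
        if multi_conditions:
            fit_rows = [
                c
                for c in std_conditions
                if flux_of(c) > min_flux and len(expressed(c)) >= 1
            ]
            if fit_rows:
                fit_genes = sorted({g for c in fit_rows for g in expressed(c)})
                E = np.array(
                    [[lookup(g, c) or 0.0 for g in fit_genes] for c in fit_rows]
                )
                vvec = np.array([flux_of(c) for c in fit_rows])
                fit = fit_isoenzyme_kapp(
                    E,
                    vvec,
                    epsilon_per_h=epsilon_per_h,
                    norm=norm,
                    reaction_id=rid,
                    conditions=fit_rows,
                    isoenzymes=fit_genes,
                )

        for cond in conditions:
            v = flux_of(cond)
            if v <= min_flux:
                continue
            expr = expressed(cond)
            if len(expr) == 1:
                k = kapp_single(v, lookup(expr[0], cond))
                if k is not None:
                    entries.append(KappEntry(rid, cond, k, "single_enzyme"))
            elif len(expr) >= 2 and fit is not None:
                if not qp_outside_std and cond not in std_conditions:
                    continue
                used = [g for g in expr if g in fit_genes]
                if not used:
                    continue
                idx = [fit_genes.index(g) for g in used]
                E_row = np.array([lookup(g, cond) for g in used])
                k_eff_h = effective_kapp(E_row, fit.k_per_h[idx])
                if k_eff_h is None or k_eff_h <= epsilon_per_h * (1.0 + 1e-9):
                    continue  # estimates stuck at the lower bound are not reported
                at_lb = bool(np.all(fit.at_lower_bound[idx]))
                entries.append(
                    KappEntry(
                        rid, cond, k_eff_h / SECONDS_PER_HOUR, source_multi, at_lb
                    )
                )
    return KappTable(entries=entries)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappMaxRecord:
    reaction_id: str
    kapp_max_per_s: float
    argmax_condition: str
    n_conditions_observed: int
    subsystem: str = ""


@dataclass
class KappMaxTable:
    records: dict[str, KappMaxRecord] = field(default_factory=dict)

    def value(self, reaction_id: str) -> float:
        return self.records[reaction_id].kapp_max_per_s

    def as_dict(self) -> dict[str, float]:
        return {rid: rec.kapp_max_per_s for rid, rec in self.records.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction_id": r.reaction_id,
                    "kapp_max_per_s": r.kapp_max_per_s,
                    "argmax_condition": r.argmax_condition,
                    "n_conditions": r.n_conditions_observed,
                    "subsystem": r.subsystem,
                }
                for r in self.records.values()
            ],
            columns=[
                "reaction_id",
                "kapp_max_per_s",
                "argmax_condition",
                "n_conditions",
                "subsystem",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def aggregate_kappmax(
    kapp_table: KappTable,
    exclude_conditions: tuple[str, ...] = (),
    subsystems: dict[str, str] | None = None,
) -> KappMaxTable:
    """Per-reaction maximum over the non-excluded condition-specific rates."""
    if not kapp_table.entries:
        raise ValueError("empty kapp table")
    excluded = set(exclude_conditions)
    table = KappMaxTable()
    by_reaction: dict[str, list[KappEntry]] = {}
    for e in kapp_table.entries:
        if e.condition_id in excluded:
            continue
        by_reaction.setdefault(e.reaction_id, []).append(e)
    for rid in sorted(by_reaction):
        group = sorted(by_reaction[rid], key=lambda e: (e.kapp_per_s, e.condition_id))
        best = group[-1]
        table.records[rid] = KappMaxRecord(
            reaction_id=rid,
            kapp_max_per_s=best.kapp_per_s,
            argmax_condition=best.condition_id,
            n_conditions_observed=len(group),
            subsystem=(subsystems or {}).get(rid, ""),
        )
    return table


def enzyme_kappmax(
    kappmax_table: KappMaxTable, iso_sets: dict[str, IsoenzymeSet]
) -> dict[str, float]:
    """Per enzyme, the maximum rate across all reactions it catalyzes (1/s)."""
    out: dict[str, float] = {}
    for rid, rec in kappmax_table.records.items():
        iso = iso_sets.get(rid)
        if iso is None:
            continue
        for cplx in iso.complexes:
            key = enzyme_key(cplx)
            out[key] = max(out.get(key, 0.0), rec.kapp_max_per_s)
    return out


# ---------------------------------------------------------------------------
# Clustering preparation
# ---------------------------------------------------------------------------

#: Distance assigned to reaction pairs with no mutually observed condition.
NO_OVERLAP_DISTANCE = 1e50


@dataclass
class ClusterPrep:
    matrix: pd.DataFrame           # centered log10 values, NaN where unobserved
    distances: np.ndarray          # square reaction x reaction distance matrix
    linkage: np.ndarray            # scipy single-linkage tree
    pseudocount: float


def cluster_prep(kapp_table: KappTable) -> ClusterPrep:
    """Centered log matrix, NA-safe distances, and a single-linkage tree.

    A pseudocount of 1e-4 times the smallest rate is added before log10;
    rows are mean-centered over observed entries; pairwise distances are
    Euclidean over mutually observed conditions, with 1e50 for pairs sharing
    none.
    """
    if not kapp_table.entries:
        raise ValueError("empty kapp table")
    df = kapp_table.to_frame().pivot_table(
        index="reaction_id", columns="condition", values="kapp_per_s"
    )
    df = df.loc[df.notna().sum(axis=1) >= 2]
    if df.shape[0] < 2:
        raise ValueError("need >= 2 reactions observed in >= 2 conditions")
    pseudocount = 1e-4 * float(np.nanmin(df.values))
    logged = np.log10(df + pseudocount)
    centered = logged.sub(logged.mean(axis=1, skipna=True), axis=0)

    values = centered.values
    n = values.shape[0]
    distances = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(values[i]) & ~np.isnan(values[j])
            if mask.any():
                d = float(np.sqrt(np.sum((values[i, mask] - values[j, mask]) ** 2)))
            else:
                d = NO_OVERLAP_DISTANCE
            distances[i, j] = distances[j, i] = d
    condensed = distances[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="single")
    return ClusterPrep(
        matrix=centered, distances=distances, linkage=Z, pseudocount=pseudocount
    )
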