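"""End-to-end orchestration: model curation -> proteomics -> flux estimation
-> apparent-rate tables -> database matching -> protein-constrained models ->
usage predictions, driven by a single config with provenance hashing."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import kapp as kapp_mod
from . import kcat_db, pcgem, proteomics
from .errors import KappmaxError
from .model_io import (
    DEFAULT_CURATION_RULES,
    apply_condition_bounds,
    apply_curation,
    irreversible_isoenzyme_sets,
    isoenzyme_sets,
    load_gem,
    read_condition_table,
    split_reversible,
)
from .nidle import measured_enzyme_map, solve_nidle

logger = logging.getLogger("kappmax")


class StageError(KappmaxError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    model_path: str
    conditions_path: str
    abundance_dir: str
    output_dir: str
    kcat_path: str | None = None
    mw_path: str | None = None
    stages: list[str] = field(default_factory=lambda: ["kapp", "pcgem", "predict"])
    epsilon_per_s: float = 1e-10
    activity_threshold: float = 1e-6
    big_M: float = 1000.0
    growth_tol: float = 0.01
    min_replicates: int = 2
    norm: str = "l2"
    std_conditions: list[str] | None = None
    exclude_condition: str | None = None
    sigma: float = 1.0
    f: float | None = None
    p_total: float = 0.5
    nutrient_uptakes: list[str] = field(default_factory=list)
    organism: str = "Chlamydomonas reinhardtii"
    taxon: str = "Viridiplantae"
    apply_default_curation: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("model_path", "conditions_path", "abundance_dir", "output_dir",
                    "kcat_path", "mw_path"):
            if data.get(key):
                p = Path(data[key])
                if not p.is_absolute():
                    data[key] = str(base / p)
        return cls(**data)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # artifacts should not depend on where they land
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    fluxes: dict[str, dict[str, float]]
    abundance: proteomics.AbundanceTable
    kapp_table: kapp_mod.KappTable
    kappmax_table: kapp_mod.KappMaxTable
    enzyme_kappmax: dict[str, float]
    kcat_matches: dict
    metrics: dict
    output_dir: Path


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run start; config_hash=%s seed=%d", chash, config.seed)
    metrics: dict = {"config_hash": chash}
    try:
        return _run(config, outdir, chash, metrics)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, chash: str, metrics: dict) -> RunResult:
    # --- model ---
    stage = "model_io"
    try:
        network = load_gem(config.model_path)
        if config.apply_default_curation and network.has_reaction("CAT"):
            network = apply_curation(network, DEFAULT_CURATION_RULES)
        iso = isoenzyme_sets(network)
        irrev = split_reversible(network)
        iso_irrev = irreversible_isoenzyme_sets(iso, irrev)
        conditions = read_condition_table(config.conditions_path)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    logger.info("model '%s': %d reactions (%d irreversible), %d conditions",
                network.model_id, len(network.reactions), len(irrev.reactions),
                len(conditions))

    # --- proteomics ---
    stage = "proteomics"
    try:
        samples = []
        for cond in conditions:
            files = sorted(Path(config.abundance_dir).glob(f"{cond.condition_id}_rep*.tsv"))
            for path in files:
                rep = int(path.stem.rsplit("_rep", 1)[1])
                samples.append(
                    proteomics.read_replicate_tsv(path, cond.condition_id, rep)
                )
        abundance = proteomics.build_abundance_table(
            samples, conditions, model_genes=set(network.genes),
            min_replicates=config.min_replicates,
        )
        _write_tsv(abundance.to_frame(), outdir / "abundance.tsv", chash)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- flux estimation ---
    stage = "nidle"
    try:
        fluxes: dict[str, dict[str, float]] = {}
        idle_counts: dict[str, int] = {}
        for cond in conditions:
            bounded = apply_condition_bounds(irrev, cond, growth_tol=config.growth_tol)
            measured = abundance.measured_proteins(cond.condition_id)
            emap = measured_enzyme_map(iso_irrev, measured)
            sol = solve_nidle(
                bounded, emap,
                activity_threshold=config.activity_threshold, big_M=config.big_M,
            )
            fluxes[cond.condition_id] = sol.flux
            idle_counts[cond.condition_id] = sol.idle_count
            logger.info("condition %s: %d measured enzymes, %d idle",
                        cond.condition_id, len(emap), sol.idle_count)
        flux_rows = [
            {"reaction_id": rid, "condition": cid, "flux": v}
            for cid in sorted(fluxes) for rid, v in sorted(fluxes[cid].items())
        ]
        _write_tsv(pd.DataFrame(flux_rows), outdir / "fluxes.tsv", chash)
        metrics["idle_counts"] = idle_counts
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- apparent rates ---
    stage = "kapp"
    try:
        std = config.std_conditions or [c.condition_id for c in conditions]
        kapp_table = kapp_mod.build_kapp_table(
            fluxes, abundance, iso_irrev, std,
            epsilon_per_h=config.epsilon_per_s * 3600.0, norm=config.norm,
        )
        exclude = (config.exclude_condition,) if config.exclude_condition else ()
        subsystems = {r.id: r.subsystem for r in irrev.reactions}
        kmax = kapp_mod.aggregate_kappmax(kapp_table, exclude, subsystems)
        ez_kmax = kapp_mod.enzyme_kappmax(kmax, iso_irrev)
        _write_tsv(kapp_table.to_frame(), outdir / "kapp.tsv", chash)
        _write_tsv(kmax.to_frame(), outdir / "kappmax.tsv", chash)
        metrics["n_kapp_entries"] = len(kapp_table.entries)
        metrics["n_kappmax_reactions"] = len(kmax.records)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # --- database matching ---
    kcat_matches: dict = {}
    if config.kcat_path:
        stage = "kcat_db"
        try:
            entries = kcat_db.read_kcat_table(config.kcat_path)
            kcat_matches = kcat_db.match_network_kcats(
                irrev, entries, config.organism, config.taxon
            )
            kcat_db.write_match_table(kcat_matches, outdir / "kcat_matches.tsv")
            shared = set(kmax.as_dict()) & set(kcat_matches)
            if len(shared) >= 2:
                cmp_res = kcat_db.compare_kapp_kcat(
                    kmax.as_dict(), {r: m.value for r, m in kcat_matches.items()}
                )
                metrics["median_lfd"] = cmp_res.median_lfd
                metrics["kapp_kcat_spearman"] = cmp_res.spearman_rho
                metrics["kapp_kcat_n"] = cmp_res.n
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- protein-constrained models + predictions ---
    if "pcgem" in config.stages and config.kcat_path and config.mw_path:
        stage = "pcgem"
        try:
            mw_df = pd.read_csv(config.mw_path, sep="\t", comment="#")
            mw = dict(zip(mw_df["gene"].astype(str), mw_df["mw_g_per_mmol"].astype(float)))
            f = config.f
            if f is None:
                f = pcgem.compute_f_factor(abundance, mw, set(network.genes))
            kcat_map = {rid: m.value for rid, m in kcat_matches.items()}
            base_model = pcgem.build_pcgem(
                irrev, iso_irrev, kcat_map, mw, config.p_total, f, config.sigma,
                tuple(config.nutrient_uptakes),
            )
            nidle_model = pcgem.substitute_kappmax(base_model, ez_kmax)
            metrics["f_factor"] = f
            metrics["growth_gecko"] = pcgem.predict_growth(base_model)
            metrics["growth_kappmax"] = pcgem.predict_growth(nidle_model)
            if "predict" in config.stages:
                usage_rows = []
                usage_metrics: dict[str, dict] = {}
                for cond in conditions:
                    measured = {
                        g: abundance.mmol(g, cond.condition_id)
                        for g in base_model.enzymes
                        if abundance.mmol(g, cond.condition_id)
                    }
                    entry: dict[str, float] = {}
                    for label, model in (("gecko", base_model), ("kappmax", nidle_model)):
                        try:
                            pred = pcgem.predict_enzyme_usage(model, cond.growth_rate)
                            m = pcgem.evaluate_usage(pred.usages, measured)
                            entry[f"usage_rho_{label}"] = m.spearman_rho
                            entry[f"usage_rmse_{label}"] = m.rmse_log10
                            for g, u in sorted(pred.usages.items()):
                                usage_rows.append(
                                    {"model": label, "condition": cond.condition_id,
                                     "gene": g, "usage_mmol_per_gDW": u}
                                )
                        except (KappmaxError, ValueError) as exc:
                            logger.warning("usage prediction skipped (%s, %s): %s",
                                           label, cond.condition_id, exc)
                    usage_metrics[cond.condition_id] = entry
                metrics["usage"] = usage_metrics
                _write_tsv(pd.DataFrame(usage_rows), outdir / "usage.tsv", chash)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    logger.info("run complete")
    return RunResult(
        config=config,
        fluxes=fluxes,
        abundance=abundance,
        kapp_table=kapp_table,
        kappmax_table=kmax,
        enzyme_kappmax=ez_kmax,
        kcat_matches=kcat_matches,
        metrics=metrics,
        output_dir=outdir,
    )


def write_default_config(fixture_dir: str | Path, path: str | Path | None = None) -> Path:
    """Write a run config pointing at a fixture directory layout."""
    fixture_dir = Path(fixture_dir)
    path = Path(path) if path else fixture_dir / "config.yaml"
    data = {
        "model_path": "model.xml",
        "conditions_path": "conditions.tsv",
        "abundance_dir": "abundance",
        "kcat_path": "kcat_table.tsv",
        "mw_path": "mw.tsv",
        "output_dir": "results",
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
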