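"""End-to-end orchestration: one config, one seeded run, one report.

A run generates (or loads) the study inputs, then executes the stages in
dependency order:

    simulate -> average/normalize/zscore -> co-regulation -> dz ranking
             -> differential expression x2 -> concordance/consensus
             -> coverage filter -> differential methylation (flight +
                recovery profiles) -> reversal -> pathway density
             -> density/expression correlation -> DEG-methylation overlap
             -> catalog QC -> unique transcripts + class-code tallies
             -> report

Every stochastic stage derives its generator from the single config seed,
outputs are written atomically, and a rerun with an identical config is
byte-identical. The report is a deterministic JSON summary with per-stage
counts, parameter echo, and sha256 digests of every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import coreg, denovo, disruption, methylation
from .io import (
    PREFLIGHT_LABELS,
    RETURN_LABEL,
    CountMatrix,
    write_counts,
    write_sample_sheet,
    write_tracking,
)
from .methylation import ProfileDef, write_meth_sites
from .simulate import (
    MissionDesign,
    SimTruth,
    plan_methylation_effects,
    random_geneset_db,
    simulate_catalog,
    simulate_counts,
    simulate_dual_quantifier,
    simulate_methylation,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "default_config", "validate_config", "run_pipeline",
           "ConfigError", "StageError"]


class ConfigError(ValueError):
    """Configuration invalid; nothing was computed."""


class StageError(RuntimeError):
    """A pipeline stage failed; the error names the stage."""


@dataclass
class RunConfig:
    """All knobs of one pipeline run. See :func:`default_config`."""

    seed: int
    out_dir: str
    simulate: dict[str, Any] = field(default_factory=dict)
    alpha: float = 0.05
    q_threshold: float = 0.01
    min_cov: int = 20
    min_avg_read_len: float = 400.0
    n_perm: int = 500
    coreg_min_size: int = 5
    coreg_max_size: int = 500
    restrict_dz_to_significant: bool = False
    windows: list[list[str]] = field(default_factory=list)
    profiles: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw or "out_dir" not in raw:
            raise ConfigError("config requires 'seed' and 'out_dir'")
        return cls(**raw)


def default_config(seed: int, out_dir: str) -> RunConfig:
    """The default synthetic study: the full mission design at desk scale."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        simulate={
            "n_genes": 2000,
            "n_pathways": 60,
            "genes_per_pathway": 20,
            "n_disrupted": 6,
            "disrupted_shift": 0.8,
            "n_trending": 6,
            "trending_slope": 0.01,
            "dispersion": 10.0,
            "n_de_genes": 40,
            "de_log2fc": 2.0,
            "n_homolog_groups": 2,
            "meth": {
                "n_sites": 400,
                "coverage_mean": 50.0,
                "n_hyper": 20,
                "n_hypo": 10,
                "delta": 30.0,
                "reversal_frac": 0.5,
            },
            "catalog": {
                "n_shared": 60,
                "unique": {"L-92": 8, "L-3": 7, "R+1": 6, "R+82": 1},
                "dropout_rate": 0.0,
            },
            "qc_fail_samples": {"C003_R+45": 279.0},
        },
        windows=[
            ["L-92", "L-44", "L-3", "R+1"],
            ["R+1", "R+45", "R+82", "R+194"],
        ],
        profiles={
            "FP1": {"test": [RETURN_LABEL], "ref": list(PREFLIGHT_LABELS)},
            "RP1": {"test": ["R+45"], "ref": [RETURN_LABEL]},
            "RP2": {"test": ["R+82"], "ref": [RETURN_LABEL]},
        },
    )


def validate_config(config: RunConfig) -> list[str]:
    """Violations as data; empty list iff the config is runnable."""
    v: list[str] = []
    if not 0 < config.alpha < 1:
        v.append(f"alpha out of range (0,1): {config.alpha}")
    if not 0 < config.q_threshold < 1:
        v.append(f"q out of range (0,1): {config.q_threshold}")
    if config.min_cov < 1:
        v.append(f"min_cov below minimum 1: {config.min_cov}")
    if config.n_perm < 100:
        v.append(f"n_perm below minimum 100: {config.n_perm}")
    if config.min_avg_read_len < 0:
        v.append(f"min_avg_read_len negative: {config.min_avg_read_len}")
    if not isinstance(config.seed, int):
        v.append("seed must be an integer")
    if config.coreg_min_size < 1 or config.coreg_max_size < config.coreg_min_size:
        v.append(
            f"bad co-regulation size window "
            f"[{config.coreg_min_size}, {config.coreg_max_size}]"
        )
    for w in config.windows:
        if len(w) < 2:
            v.append(f"window too small: {w}")
    for name, prof in config.profiles.items():
        if set(prof) != {"test", "ref"}:
            v.append(f"profile {name} must define 'test' and 'ref'")
        elif set(prof["test"]) & set(prof["ref"]):
            v.append(f"profile {name}: test and ref overlap")
    return v


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _atomic(path: Path, writer) -> Path:
    """Run a writer against a temp path, then rename into place."""
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    os.replace(tmp, path)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the report dict (also written to disk)."""
    violations = validate_config(config)
    if violations:
        raise ConfigError("; ".join(violations))

    out = Path(config.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": {
            k: v for k, v in asdict(config).items() if k != "out_dir"
        },
        "stages": {},
        "warnings": [],
        "files": {},
    }
    written: list[Path] = []

    def stage(name: str):
        def wrap(fn):
            try:
                _log(name, "start")
                info = fn()
                report["stages"][name] = info
                _log(name, "done")
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    sim = config.simulate
    design = MissionDesign()
    state: dict[str, Any] = {}

    @stage("simulate")
    def _():
        db = random_geneset_db(
            sim.get("n_pathways", 60), sim.get("genes_per_pathway", 20),
        )
        names = sorted(db.sets)
        n_dis, n_tr = sim.get("n_disrupted", 6), sim.get("n_trending", 6)
        # gene-level DE effects live on background genes, outside pathways
        n_pw_genes = sum(len(gs) for _, gs in db.items())
        n_genes = sim.get("n_genes", 2000)
        bg = [f"BG{i:05d}" for i in range(max(0, n_genes - n_pw_genes))]
        de_genes = {
            g: sim.get("de_log2fc", 2.0)
            for g in bg[: sim.get("n_de_genes", 40)]
        }
        truth = SimTruth(
            disrupted_pathways={
                n: sim.get("disrupted_shift", 0.8) for n in names[:n_dis]
            },
            trending_pathways={
                n: sim.get("trending_slope", 0.01)
                for n in names[n_dis:n_dis + n_tr]
            },
            de_genes=de_genes,
        )
        counts, truth = simulate_counts(
            n_genes, db, design, effects=truth,
            dispersion=sim.get("dispersion", 10.0), seed=config.seed,
        )
        pathway_genes = sorted(db[names[-1]])
        groups = []
        for i in range(sim.get("n_homolog_groups", 2)):
            groups.append(set(pathway_genes[3 * i: 3 * i + 3]))
        a, b = simulate_dual_quantifier(counts, groups, seed=config.seed + 1)

        meth_cfg = sim.get("meth", {})
        meth_truth = plan_methylation_effects(
            meth_cfg.get("n_hyper", 20), meth_cfg.get("n_hypo", 10),
            delta=meth_cfg.get("delta", 30.0),
            reversal_frac=meth_cfg.get("reversal_frac", 0.5),
        )
        # methylated genes drawn from disrupted-pathway genes, DE genes and
        # background so the density and overlap stages have signal to find
        pathway_pool = sorted(
            g for n in truth.disrupted_pathways for g in db[n]
        )
        gene_pool = (
            pathway_pool + sorted(de_genes)
            + [g for g in bg if g not in de_genes][:40]
        )
        meth_table, meth_truth = simulate_methylation(
            meth_cfg.get("n_sites", 400), design,
            coverage_mean=meth_cfg.get("coverage_mean", 50.0),
            effects=meth_truth, seed=config.seed + 2,
            gene_pool=gene_pool,
        )
        cat_cfg = sim.get("catalog", {})
        catalog, cat_truth = simulate_catalog(
            design,
            n_shared=cat_cfg.get("n_shared", 60),
            unique_spec=cat_cfg.get("unique", {}),
            dropout_rate=cat_cfg.get("dropout_rate", 0.0),
            seed=config.seed + 3,
        )
        metas = design.sample_meta(read_lengths=sim.get("qc_fail_samples", {}))

        written.append(_atomic(out / "inputs" / "counts_a.tsv",
                               lambda p: write_counts(a, p)))
        written.append(_atomic(out / "inputs" / "counts_b.tsv",
                               lambda p: write_counts(b, p)))
        written.append(_atomic(out / "inputs" / "meth_sites.tsv",
                               lambda p: write_meth_sites(meth_table, p)))
        written.append(_atomic(out / "inputs" / "catalog.tracking",
                               lambda p: write_tracking(catalog, p)))
        written.append(_atomic(out / "inputs" / "sample_sheet.tsv",
                               lambda p: write_sample_sheet(metas, p)))
        truth_json = {
            "disrupted_pathways": truth.disrupted_pathways,
            "trending_pathways": truth.trending_pathways,
            "de_genes": truth.de_genes,
            "true_hyper_sites": {
                k: list(v) for k, v in meth_truth.true_hyper_sites.items()
            },
            "true_hypo_sites": {
                k: list(v) for k, v in meth_truth.true_hypo_sites.items()
            },
            "unique_transcripts": {
                k: sorted(v) for k, v in cat_truth.unique_transcripts.items()
            },
        }
        _atomic_write_text(
            out / "inputs" / "truth.json",
            json.dumps(truth_json, sort_keys=True, indent=1),
        )
        written.append(out / "inputs" / "truth.json")
        state.update(
            db=db, counts=counts, a=a, b=b, truth=truth, metas=metas,
            meth_table=meth_table, meth_truth=meth_truth,
            catalog=catalog, cat_truth=cat_truth,
        )
        return {
            "n_genes": counts.shape[0],
            "n_samples": counts.shape[1],
            "n_pathways": len(db),
            "n_meth_sites": len(meth_table.site_ids),
            "n_catalog_transcripts": len(catalog.info),
        }

    @stage("zscore")
    def _():
        avg, dropped = coreg.average_quantifiers(state["a"], state["b"])
        norm = coreg.normalize_library_size(avg)
        z = coreg.zscore(norm)
        state.update(z=z)
        return {
            "genes_dropped_from_intersection": len(dropped),
            "constant_genes": len(z.constant_genes),
            "genes_zscored": len(z.gene_ids),
        }

    @stage("coreg")
    def _():
        results, skipped = coreg.coregulation_test(
            state["z"], state["db"], n_perm=config.n_perm,
            min_size=config.coreg_min_size, max_size=config.coreg_max_size,
            seed=config.seed + 10,
        )
        sig = [r for r in results if r.padj < config.alpha]
        rows = "\n".join(
            f"{r.pathway}\t{r.score!r}\t{r.p!r}\t{r.padj!r}\t{r.n_genes_used}"
            for r in results
        )
        _atomic_write_text(
            out / "results" / "coreg.tsv",
            "pathway\tscore\tp\tpadj\tn_genes_used\n" + rows + "\n",
        )
        written.append(out / "results" / "coreg.tsv")
        state.update(coreg_results=results, coreg_sig={r.pathway for r in sig})
        return {
            "pathways_tested": len(results),
            "pathways_skipped": len(skipped),
            "pathways_significant": len(sig),
        }

    @stage("dz")
    def _():
        names = (
            sorted(state["coreg_sig"]) if config.restrict_dz_to_significant
            else sorted(r.pathway for r in state["coreg_results"])
        )
        records = []
        for name in names:
            traj = coreg.pathway_trajectory(
                state["z"], state["db"][name], state["metas"], pathway=name
            )
            records.append(disruption.dz_score(traj))
        ranked = disruption.rank_by_dz(records)
        table = disruption.dz_table(ranked)
        _atomic_write_text(
            out / "results" / "dz.tsv",
            table.to_csv(sep="\t", index=False),
        )
        written.append(out / "results" / "dz.tsv")
        state.update(dz=ranked)
        top = {r.pathway for r in ranked[: len(state["truth"].disrupted_pathways)]}
        planted = set(state["truth"].disrupted_pathways)
        return {
            "pathways_scored": len(ranked),
            "top_k_planted_recovery": (
                len(top & planted) / len(planted) if planted else None
            ),
        }

    @stage("de_consensus")
    def _():
        # return vs all pre-flight draws, each run an independent replicate
        # (the grouped-timepoint convention for multi-timepoint contrasts)
        design_days = design.days
        test = [
            s for s in state["a"].sample_ids
            if design_days[s.split("_", 1)[1]] == 1
        ]
        ref = [
            s for s in state["a"].sample_ids
            if design_days[s.split("_", 1)[1]] < 0
        ]
        dge_a = coreg.simple_de(state["a"], test, ref, source="A")
        dge_b = coreg.simple_de(state["b"], test, ref, source="B")
        conc = coreg.concordance(
            state["a"], state["b"], dge_a, dge_b, alpha=config.alpha
        )
        _atomic_write_text(
            out / "results" / "dge_consensus.tsv",
            "gene\tcategory\n" + "".join(
                f"{g}\t{c}\n" for g, c in conc.categories.sort_index().items()
            ),
        )
        written.append(out / "results" / "dge_consensus.tsv")
        state.update(conc=conc)
        planted = set(state["truth"].de_genes)
        hit = len(conc.consensus_degs & planted)
        return {
            "median_pearson_r": round(conc.median_r, 6),
            "log2fc_pearson_r": round(conc.log2fc_r, 6),
            "consensus_degs": len(conc.consensus_degs),
            "de_sensitivity": hit / len(planted) if planted else None,
        }

    @stage("diffmeth")
    def _():
        table = methylation.filter_coverage(
            state["meth_table"], min_cov=config.min_cov
        )
        def labels_of(tps: set[str]) -> list[str]:
            return [
                s for s in state["meth_table"].sample_ids
                if s.split("_", 1)[1] in tps
            ]
        profiles = {
            name: ProfileDef(
                name, tuple(p["test"]), tuple(p["ref"])
            )
            for name, p in config.profiles.items()
        }
        records = {}
        for name, prof in profiles.items():
            rec = methylation.diff_methylation(
                table,
                labels_of(set(prof.test_timepoints)),
                labels_of(set(prof.reference_timepoints)),
                q_threshold=config.q_threshold,
            )
            records[name] = rec
            _atomic_write_text(
                out / "results" / f"diffmeth_{name}.tsv",
                rec.to_csv(sep="\t", index=False),
            )
            written.append(out / "results" / f"diffmeth_{name}.tsv")
        state.update(meth_filtered=table, meth_records=records)
        fp = records.get("FP1")
        hyper, hypo = methylation.classify_profile(fp)
        state.update(hyper=hyper, hypo=hypo)
        return {
            "sites_after_coverage_filter": len(table.site_ids),
            "sites_tested": int(len(fp)),
            "hyper_sites": len(hyper),
            "hypo_sites": len(hypo),
        }

    @stage("reversal")
    def _():
        recovery = {
            name: rec for name, rec in state["meth_records"].items()
            if name != "FP1"
        }
        rep = methylation.reversal_analysis(
            state["meth_records"]["FP1"], recovery
        )
        state.update(reversal=rep)
        out_json = {
            day: {
                "reversed_hyper": sorted(rep.reversed_hyper[day]),
                "reversed_hypo": sorted(rep.reversed_hypo[day]),
                "genes_hyper": sorted(rep.genes_hyper[day]),
                "genes_hypo": sorted(rep.genes_hypo[day]),
            }
            for day in sorted(rep.reversed_hyper)
        }
        _atomic_write_text(
            out / "results" / "reversal.json",
            json.dumps(out_json, sort_keys=True, indent=1),
        )
        written.append(out / "results" / "reversal.json")
        return {
            day: len(v) for day, v in rep.reversed_hyper.items()
        } | {"profiles": sorted(recovery)}

    @stage("meth_density")
    def _():
        fp = state["meth_records"]["FP1"]
        sig = fp[fp["significant"]]
        universe = set(state["meth_filtered"].sites["gene_id"])
        densities, skipped = methylation.pathway_meth_density(
            sig, state["db"], universe
        )
        state.update(densities=densities)
        scores = {r.pathway: r.score for r in state["coreg_results"]}
        try:
            corr = methylation.density_expression_correlation(densities, scores)
        except Exception:
            corr = {"note": "too few shared pathways"}
        max_density = max(densities.values()) if densities else 0.0
        return {
            "pathways_with_density": len(densities),
            "pathways_skipped": len(skipped),
            "max_sites_per_gene": round(max_density, 4),
            "correlation": {
                k: (None if isinstance(v, float) and v != v else v)
                for k, v in corr.items()
            },
        }

    @stage("deg_meth_overlap")
    def _():
        fp = state["meth_records"]["FP1"]
        meth_genes = set(fp.loc[fp["significant"], "gene_id"])
        rep = methylation.deg_meth_overlap(
            meth_genes, set(state["conc"].consensus_degs)
        )
        return {
            "n_overlap": rep["n_overlap"],
            "n_meth": rep["n_meth"],
            "n_deg": rep["n_deg"],
        }

    @stage("denovo")
    def _():
        excluded = denovo.flag_low_quality(
            state["metas"], min_avg_read_len=config.min_avg_read_len
        )
        catalog = state["catalog"].with_sample_meta(state["metas"])
        catalog = catalog.drop_samples(excluded)
        results = {}
        for window in config.windows:
            usable = [
                tp for tp in window if catalog.samples_at(tp)
            ]
            rep = denovo.unique_transcripts(catalog, usable)
            tally = denovo.class_code_tally(
                {t for s in rep.unique.values() for t in s}, catalog
            )
            results["|".join(window)] = {
                "unique_counts": {tp: len(rep.unique[tp]) for tp in usable},
                "class_code_tally": {
                    c: n for c, n in tally.items() if n
                },
            }
        _atomic_write_text(
            out / "results" / "unique_transcripts.json",
            json.dumps(results, sort_keys=True, indent=1),
        )
        written.append(out / "results" / "unique_transcripts.json")
        state.update(denovo=results)
        return {"excluded_samples": excluded, "windows": results}

    for path in sorted(set(written)):
        report["files"][str(path.relative_to(out))] = _sha256(path)
    report_text = json.dumps(report, sort_keys=True, indent=1)
    _atomic_write_text(out / "report.json", report_text)
    return report
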