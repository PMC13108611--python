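"""Pipeline configuration, orchestration, and reproducibility plumbing.

``run_pipeline`` sequences the full analysis — preparation, rank scan,
rank selection, final factorization, stability validation, signature
characterization, loading normalization, mixed-model association, and
(when both layers are present) cross-layer integration — writing every
artifact as TSV/JSON under the output directory together with a
manifest of inputs, parameters, seeds and content hashes, so a run can
be replayed and verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrices import AbundanceMatrix, read_abundance, write_abundance
from .prep import filter_features, tss_normalize, sparsity
from .nmf import multi_run, scan_ranks
from .ranksel import select_rank
from .stability import subsample_stability
from .signatures import (
    composition_by_group,
    dominant_es,
    enrichment_specificity,
    loading_diversity,
    rank_features,
)
from .associations import fit_es_model, fit_phenotype_model, tmm_clr
from .crosslayer import centroid_trend_test, permanova, spearman_matrix

log = logging.getLogger("enterosig")


@dataclass
class PipelineConfig:
    """Declarative run description (YAML-loadable).

    Tolerances default to 0.10 for the taxonomic (MAG) layer and 0.05
    for the functional (KO) layer; the candidate grid, runs per rank,
    final runs, stability settings and the master seed default to the
    study protocol this pipeline reproduces.
    """

    abundance: str
    metadata: str
    out_dir: str
    kind: str = "MAG"
    phenotypes: str | None = None
    ko_abundance: str | None = None
    rank_grid: tuple[int, int] = (2, 8)
    runs_per_rank: int = 10
    final_runs: int = 30
    tolerance_mag: float = 0.10
    tolerance_ko: float = 0.05
    stability_iters: int = 100
    stability_fraction: float = 0.8
    top_n: int = 30
    prevalence_min: float = 0.20
    abundance_quantile: float = 0.75
    n_perm: int = 9999
    seed: int = 12345
    max_iter: int = 2000
    tol: float = 1e-6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "rank_grid" in raw:
            raw["rank_grid"] = tuple(raw["rank_grid"])
        cfg = cls(**raw)
        base = Path(path).parent
        for attr in ("abundance", "metadata", "phenotypes", "ko_abundance"):
            val = getattr(cfg, attr)
            if val is not None:
                p = (base / val) if not Path(val).is_absolute() else Path(val)
                setattr(cfg, attr, str(p))
                if not p.exists():
                    raise FileNotFoundError(f"{attr} file not found: {p}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _analyze_layer(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    cfg: PipelineConfig,
    tolerance: float,
    out: Path,
    tag: str,
) -> dict:
    """Prep -> rank scan -> final fit -> stability -> signatures for one
    feature layer; returns the artifacts downstream stages need."""
    t0 = time.time()
    filtered, report = filter_features(
        matrix, cfg.prevalence_min, cfg.abundance_quantile, return_report=True
    )
    V = tss_normalize(filtered)
    log.info(
        "[%s] prep: %d -> %d features, sparsity %.3f -> %.3f",
        tag, report.n_features_before, report.n_features_after,
        report.sparsity_before, report.sparsity_after,
    )
    _write_json(report.to_dict(), out / f"{tag}_filter_report.json")

    lo, hi = cfg.rank_grid
    metrics = scan_ranks(
        V, range(lo, hi + 1), n_runs=cfg.runs_per_rank, base_seed=cfg.seed,
        max_iter=cfg.max_iter, tol=cfg.tol,
    )
    metrics.to_csv(out / f"{tag}_rank_metrics.tsv", sep="\t")
    sel = select_rank(metrics, tolerance=tolerance)
    _write_json(sel.to_dict(), out / f"{tag}_rank_selection.json")
    log.info("[%s] selected rank k=%d (votes %s)", tag, sel.chosen_k, sel.votes)

    best, consensus = multi_run(
        V, sel.chosen_k, n_runs=cfg.final_runs, base_seed=cfg.seed,
        max_iter=cfg.max_iter, tol=cfg.tol,
    )
    sig_ids = [f"ES{i + 1}" for i in range(sel.chosen_k)]
    W_df = pd.DataFrame(best.W, index=V.sample_ids, columns=sig_ids)
    H_df = pd.DataFrame(best.H, index=sig_ids, columns=V.feature_ids)
    W_df.to_csv(out / f"{tag}_W.tsv", sep="\t")
    H_df.to_csv(out / f"{tag}_H.tsv", sep="\t")

    stab = subsample_stability(
        V, sel.chosen_k, n_iter=cfg.stability_iters,
        fraction=cfg.stability_fraction, top_n=cfg.top_n, seed=cfg.seed,
        metadata=metadata, max_iter=cfg.max_iter, tol=cfg.tol,
        reference=best.H,
    )
    stab.per_iteration.to_csv(out / f"{tag}_stability_iterations.tsv", sep="\t")
    _write_json(stab.to_dict(), out / f"{tag}_stability.json")
    log.info("[%s] stability: mean Jaccard %.3f", tag, stab.mean_jaccard)

    table = enrichment_specificity(best.H, V.feature_ids)
    ranked = rank_features(table, top_n=cfg.top_n)
    ranked.to_csv(out / f"{tag}_signatures.tsv", sep="\t", index=False)
    labels = dominant_es(best.W)
    comp = composition_by_group(labels, metadata)
    comp.to_csv(out / f"{tag}_composition.tsv", sep="\t", index=False)
    div = loading_diversity(best.W)
    div.insert(0, "sample_id", V.sample_ids)
    div.to_csv(out / f"{tag}_diversity.tsv", sep="\t", index=False)

    log.info("[%s] layer complete in %.1fs", tag, time.time() - t0)
    return {"V": V, "W": best.W, "H": best.H, "k": sel.chosen_k, "sig_ids": sig_ids}


def _associate_layer(
    layer: dict, metadata: pd.DataFrame, phenotypes: pd.DataFrame | None,
    out: Path, tag: str,
) -> None:
    norm = tmm_clr(layer["W"])
    clr_df = pd.DataFrame(
        norm.clr, index=metadata["sample_id"], columns=layer["sig_ids"]
    )
    clr_df.to_csv(out / f"{tag}_W_clr.tsv", sep="\t")
    rows, contrasts, effects = [], [], []
    for j, sig in enumerate(layer["sig_ids"]):
        res = fit_es_model(norm.clr[:, j], metadata, response=sig)
        if not res.converged:
            log.warning("[%s] %s dynamics model did not converge; excluded", tag, sig)
            continue
        rows.append(res.anova)
        c = res.contrasts.copy()
        c.insert(0, "response", sig)
        contrasts.append(c)
        e = res.effect_sizes.copy()
        e.insert(0, "response", sig)
        effects.append(e)
    if rows:
        pd.concat(rows).to_csv(out / f"{tag}_es_anova.tsv", sep="\t", index=False)
        pd.concat(contrasts).to_csv(out / f"{tag}_es_contrasts.tsv", sep="\t", index=False)
        pd.concat(effects).to_csv(out / f"{tag}_es_effect_sizes.tsv", sep="\t", index=False)
    if phenotypes is None:
        return
    ph_rows = []
    pheno_cols = [c for c in phenotypes.columns if c != "sample_id"]
    for pheno in pheno_cols:
        for j, sig in enumerate(layer["sig_ids"]):
            res = fit_phenotype_model(
                phenotypes[pheno].to_numpy(), norm.clr[:, j], metadata,
                response=f"{pheno}:{sig}",
            )
            if not res.converged:
                continue
            tab = res.anova.copy()
            tab.insert(0, "phenotype", pheno)
            tab.insert(1, "signature", sig)
            ph_rows.append(tab)
    if ph_rows:
        pd.concat(ph_rows).to_csv(
            out / f"{tag}_phenotype_anova.tsv", sep="\t", index=False
        )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    metadata = pd.read_csv(cfg.metadata, sep="\t")
    matrix = read_abundance(cfg.abundance, kind=cfg.kind)
    phenotypes = (
        pd.read_csv(cfg.phenotypes, sep="\t") if cfg.phenotypes else None
    )

    stage = "taxonomic layer"
    try:
        tax = _analyze_layer(matrix, metadata, cfg, cfg.tolerance_mag, out, "tax")
        stage = "taxonomic associations"
        _associate_layer(tax, metadata, phenotypes, out, "tax")

        fun = None
        if cfg.ko_abundance:
            stage = "functional layer"
            ko = read_abundance(cfg.ko_abundance, kind="KO")
            fun = _analyze_layer(ko, metadata, cfg, cfg.tolerance_ko, out, "fun")
            stage = "functional associations"
            _associate_layer(fun, metadata, phenotypes, out, "fun")

            stage = "cross-layer integration"
            rho, rho_p = spearman_matrix(tax["W"], fun["W"])
            rho.to_csv(out / "crosslayer_rho.tsv", sep="\t")
            rho_p.to_csv(out / "crosslayer_rho_p.tsv", sep="\t")

        stage = "trend tests"
        integrate = {}
        for tag, layer in (("tax", tax), ("fun", fun)):
            if layer is None:
                continue
            trend = centroid_trend_test(
                layer["W"], metadata, n_perm=cfg.n_perm, seed=cfg.seed
            )
            perm = {}
            for tp in sorted(metadata["timepoint"].unique()):
                m = (metadata["timepoint"] == tp).to_numpy()
                res = permanova(
                    layer["W"][m], metadata.loc[m, "line"].to_numpy(),
                    n_perm=cfg.n_perm, seed=cfg.seed,
                )
                perm[tp] = {"R2": res.r2, "p": res.p}
            integrate[tag] = {
                "centroid_distance": trend.centroid_distance,
                "delta": trend.delta,
                "perm_p": trend.perm_p,
                "direction": trend.direction,
                "permanova": perm,
            }
        _write_json(integrate, out / "trend_tests.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("abundance", cfg.abundance),
                ("metadata", cfg.metadata),
                ("phenotypes", cfg.phenotypes),
                ("ko_abundance", cfg.ko_abundance),
            )
            if p
        },
        "outputs": {
            f.name: _sha256(f)
            for f in sorted(out.iterdir())
            if f.is_file() and f.name != "manifest.json"
        },
    }
    _write_json(manifest, out / "manifest.json")
    log.info("pipeline complete in %.1fs", time.time() - t_start)
    return manifest
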