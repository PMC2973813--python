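"""End-to-end orchestration: synthesize (or load) inputs, run every stage,
and emit a machine-readable report mirroring the analysis panels."""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
from dataclasses import asdict, dataclass

import numpy as np

from . import __version__, divergence, evolution, interactions, ontology, predict, structnet
from .records import PairRecord
from .synth import SynthBundle, SynthConfig, generate_bundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    synth: SynthConfig
    alpha: float = 0.05
    ks_max: float = 2.0
    min_identity: float = 0.20
    n_controls: int = 1000
    pairs_per_control: int = 1000
    cv_folds: int = 3
    cv_repeats: int = 10
    exclude_genes: tuple[str, ...] = ()  # e.g. ribosomal stand-in list
    seed: int = 0


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {"synth": asdict(config.synth), **{k: v for k, v in asdict(config).items() if k != "synth"}},
        sort_keys=True, default=list,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _measure_pairs(bundle: SynthBundle, config: PipelineConfig) -> tuple[list[PairRecord], dict]:
    """Fill per-pair metrics from the bundle artifacts.

    Planted Ka/Ks act as the precomputed (external-estimator) table and take
    precedence; NG86 runs only when no precomputed value exists.
    """
    exclusions = {"unannotated": 0, "expression_undefined": 0, "excluded_gene_list": 0}
    out: list[PairRecord] = []
    excl = set(config.exclude_genes)
    for p in bundle.pairs:
        if p.gene_a in excl or p.gene_b in excl:
            exclusions["excluded_gene_list"] += 1
            continue
        rec = PairRecord(
            pair_id=p.pair_id, gene_a=p.gene_a, gene_b=p.gene_b,
            pair_class=p.pair_class, score=p.score, p_value=p.p_value,
            ka=p.ka, ks=p.ks,
        )
        rec.buffering = interactions.classify_buffering(rec, alpha=config.alpha)
        gd = ontology.go_div(bundle.dag, bundle.corpus, p.gene_a, p.gene_b)
        if gd.status != "ok":
            exclusions["unannotated"] += 1
        else:
            rec.go_div = gd.score
        if p.gene_a in bundle.sequences and p.gene_b in bundle.sequences:
            sa, sb = bundle.sequences[p.gene_a], bundle.sequences[p.gene_b]
            aa_a = "".join(divergence.translate(sa[i:i + 3]) for i in range(0, len(sa), 3))
            aa_b = "".join(divergence.translate(sb[i:i + 3]) for i in range(0, len(sb), 3))
            rec.identity = divergence.protein_identity(aa_a, aa_b)
        if p.gene_a in bundle.expression and p.gene_b in bundle.expression:
            try:
                rec.expression_divergence = divergence.expression_divergence(
                    bundle.expression[p.gene_a], bundle.expression[p.gene_b]
                )
            except divergence.UndefinedDivergenceError:
                exclusions["expression_undefined"] += 1
        out.append(rec)
    return out, exclusions


def _buffering_stage(pairs, bundle: SynthBundle, config: PipelineConfig) -> dict:
    stage: dict = {"classes": {}}
    for cls in ("WGD", "SSD"):
        members = [p for p in pairs if p.pair_class == cls]
        if not members:
            continue
        summary = interactions.buffering_summary(members, alpha=config.alpha)
        stage["classes"][cls] = {
            "n_buffering": summary.n_buffering,
            "n_total": summary.n_total,
            "percentage": summary.percentage,
            "mean_strength": summary.mean_strength,
        }
    null = interactions.randomization_null(
        bundle.interactions,
        n_controls=config.n_controls,
        pairs_per_control=min(config.pairs_per_control, len(bundle.interactions)),
        seed=config.seed,
    )
    stage["random_pair_null"] = {
        "mean_percentage": float(np.mean(null.control_percentages)),
        "n_controls": null.n_controls,
        "pairs_per_control": null.pairs_per_control,
    }
    for cls, info in stage["classes"].items():
        info["empirical_p_vs_null"] = interactions.empirical_p(
            info["percentage"], null, side="greater"
        )
    try:
        shuffle_null = interactions.duplicate_shuffle_null(
            bundle.duplicate_genes, bundle.interactions,
            n_controls=config.n_controls, seed=config.seed + 1,
        )
        stage["duplicate_shuffle_null"] = {
            "mean_percentage": float(np.mean(shuffle_null.control_percentages)),
            "n_controls_kept": len(shuffle_null.control_percentages),
        }
    except interactions.InteractionError as exc:
        stage["duplicate_shuffle_null"] = {"error": str(exc)}
    return stage


def _correlation_stage(pairs, config: PipelineConfig) -> dict:
    stage: dict = {}
    for cls in ("WGD", "SSD"):
        buf = [p for p in pairs if p.pair_class == cls and p.buffering]
        entry: dict = {"n_buffering": len(buf)}
        for feature in ("go_div", "ka", "expression_divergence"):
            xs, ys = [], []
            for p in buf:
                v = getattr(p, feature)
                if math.isfinite(v) and math.isfinite(p.score):
                    xs.append(v)
                    # raw score: closer to 0 = weaker buffering, so divergence
                    # correlates positively with it
                    ys.append(p.score)
            if len(xs) >= 3 and np.std(xs) > 0:
                c = evolution.pearson_test(xs, ys)
                entry[f"strength_vs_{feature}"] = {"r": c.r, "p": c.p, "n": c.n}
        stage[cls] = entry
    return stage


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Run every stage on a synthesized bundle and return the report.

    Stages: buffering summary + nulls, divergence measurement, strength
    correlations, classifier cross-validation, neutral-mode analysis, and
    structure/network comparisons.  Deterministic under identical config.
    """
    t0 = time.time()
    bundle = generate_bundle(config.synth)
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "synth_seed": config.synth.seed,
            "version": __version__,
        },
        "timings": {},
    }

    t = time.time()
    pairs, exclusions = _measure_pairs(bundle, config)
    report["provenance"]["exclusions"] = exclusions
    report["provenance"]["n_pairs_input"] = len(bundle.pairs)
    report["provenance"]["n_pairs_used"] = len(pairs)
    report["timings"]["measure"] = round(time.time() - t, 3)

    t = time.time()
    report["buffering"] = _buffering_stage(pairs, bundle, config)
    report["timings"]["buffering"] = round(time.time() - t, 3)

    report["correlations"] = _correlation_stage(pairs, config)

    t = time.time()
    try:
        vectors, excluded = predict.assemble_features(pairs)
        cv = predict.cross_validate(
            vectors, folds=config.cv_folds, repeats=config.cv_repeats, seed=config.seed,
        )
        report["prediction"] = {
            "auc_mean": cv.auc_mean, "auc_sd": cv.auc_sd,
            "n_vectors": len(vectors), "n_excluded": len(excluded),
            "folds": cv.folds, "repeats": cv.repeats,
            "roc_points": cv.roc_points,
        }
    except predict.PredictError as exc:
        report["prediction"] = {"error": str(exc)}
    report["timings"]["prediction"] = round(time.time() - t, 3)

    t = time.time()
    ssd_buf = [p for p in pairs if p.pair_class == "SSD" and p.buffering]
    if len(ssd_buf) >= 5:
        try:
            report["neutral_mode"] = evolution.neutral_mode_report(
                [p.score for p in ssd_buf],
                [p.ka for p in ssd_buf],
                [p.ks for p in ssd_buf],
                ks_max=config.ks_max,
            )
        except evolution.EvolutionError as exc:
            report["neutral_mode"] = {"error": str(exc)}
    else:
        report["neutral_mode"] = {"error": "fewer than 5 buffering SSD pairs"}
    report["timings"]["neutral_mode"] = round(time.time() - t, 3)

    t = time.time()
    report["structnet"] = _structnet_stage(pairs, bundle)
    report["timings"]["structnet"] = round(time.time() - t, 3)

    report["timings"]["total"] = round(time.time() - t0, 3)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "wt", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def _structnet_stage(pairs, bundle: SynthBundle) -> dict:
    stage: dict = {}
    if bundle.ppi_edges:
        ppi = structnet.PpiNetwork(bundle.ppi_edges)
        buf = [(p.gene_a, p.gene_b) for p in pairs if p.buffering]
        nonbuf = [(p.gene_a, p.gene_b) for p in pairs if not p.buffering]
        if buf and nonbuf:
            stage["shared_partners"] = structnet.shared_partner_comparison(buf, nonbuf, ppi)
    if bundle.complexes:
        catalog = structnet.ComplexCatalog(bundle.complexes)
        buf = [(p.gene_a, p.gene_b) for p in pairs if p.buffering]
        nonbuf = [(p.gene_a, p.gene_b) for p in pairs if not p.buffering]
        if buf and nonbuf:
            stage["cocluster"] = {
                "buffering_fraction": structnet.complex_cocluster_fraction(buf, catalog),
                "nonbuffering_fraction": structnet.complex_cocluster_fraction(nonbuf, catalog),
                "n_complexes": len(catalog.complexes),
            }
    if bundle.ss:
        d_buf, d_nonbuf = [], []
        for p in pairs:
            if p.gene_a in bundle.ss and p.gene_b in bundle.ss:
                va = structnet.ss_transition_vector(bundle.ss[p.gene_a])
                vb = structnet.ss_transition_vector(bundle.ss[p.gene_b])
                d = structnet.structure_discrepancy(va, vb)
                (d_buf if p.buffering else d_nonbuf).append(d)
        if d_buf and d_nonbuf:
            stage["structure_discrepancy"] = {
                "buffering_mean": float(np.mean(d_buf)),
                "nonbuffering_mean": float(np.mean(d_nonbuf)),
                "n_buffering": len(d_buf),
                "n_nonbuffering": len(d_nonbuf),
            }
    return stage
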