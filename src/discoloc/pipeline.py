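"""End-to-end orchestration: windows → colocalization → credible sets →
discordance → fine-mapping → QTL integration → enrichment/TOA →
expression statistics, driven by one config and one seed.

The pipeline runs on synthetic loci generated by :mod:`discoloc.simulate`
(config section ``simulate``) so every stage is exercisable without
external downloads; thresholds default to the analysis constants
(sig_p 5e-8, flank 500 kb, merge 250 kb, eaf 1%, p12 5e-6, regional 0.70,
credible 0.99, discordance p 1e-5, clump r² 0.50, QTL PPH4 0.50, FDR 5%,
TOA 0.20/0.10, LRT 0.05).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as cl
from . import discordance as dc
from . import exprstats as ex
from . import finemap as fm
from . import qtl as qt
from . import simulate as sim
from . import toa as ta
from .io_formats import harmonize

log = logging.getLogger("discoloc.pipeline")

DEFAULT_THRESHOLDS = {
    "sig_p": 5e-8,
    "flank": 500_000,
    "merge_gap": 250_000,
    "min_eaf": 0.01,
    "p1": 1e-4,
    "p2": 1e-4,
    "p12": 5e-6,
    "regional": 0.70,
    "credible_level": 0.99,
    "discord_p": 1e-5,
    "clump_r2": 0.50,
    "lead_ld_r2": 0.8,
    "qtl_pph4": 0.50,
    "fdr": 0.05,
    "toa_primary": 0.20,
    "toa_share": 0.10,
    "lrt_alpha": 0.05,
}

DEFAULT_SIMULATE = {
    "n_loci": 20,
    "mix": {"H0": 0.3, "H1": 0.1, "H2": 0.1, "H3": 0.1, "H4": 0.2,
            "H4_discordant": 0.2},
    "p": 100,
    "decay": 0.9,
    "lam": 7.0,
    "n_a": 100_000,
    "n_b": 100_000,
}

DEFAULT_ANNOTATION_GAMMA = {
    ("adipose", "Enhancer"): 1.5,
    ("muscle", "Enhancer"): 0.0,
    ("liver", "Enhancer"): 0.0,
}


@dataclass
class RunManifest:
    """Auditable record of one pipeline execution."""

    seed: int
    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        for key, val in self.counts.items():
            if isinstance(val, (int, float)) and val < 0:
                raise ValueError(f"negative count {key}={val}")
        n_sig = self.counts.get("signals", 0)
        n_dis = self.counts.get("discordant_signals", 0)
        if n_dis > n_sig:
            raise ValueError("discordant signals exceed total signals")

    def write(self, path: Path) -> None:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))
        payload = asdict(self)
        payload["config"] = _stringify_keys(payload["config"])
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=_default) + "\n")


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {str(k): _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


@dataclass
class LocusAnalysis:
    """Per-locus result of the windows → coloc → discordance chain."""

    locus: sim.SimulatedLocus
    pair: object
    windows: list
    result: object | None = None
    votes: dict = field(default_factory=dict)
    colocalized: bool = False
    credible: object | None = None
    signals: list = field(default_factory=list)
    window_pair: object | None = None

    @property
    def label(self) -> str:
        """Locus label = label of its lead (most significant) signal."""
        for lab in ("discordant", "concordant"):
            if any(s.label == lab for s in self.signals):
                return lab
        return "unlabeled"


def analyze_locus(locus: sim.SimulatedLocus, thresholds: dict | None = None
                  ) -> LocusAnalysis:
    """Run one locus through windows, consensus colocalization, the 99%
    credible set, discordance labels and LD clumping."""
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    priors = (th["p1"], th["p2"], th["p12"])
    pair = harmonize(locus.stats_a, locus.stats_b)
    windows = dc.build_windows(pair, sig_p=th["sig_p"], flank=th["flank"],
                               merge_gap=th["merge_gap"],
                               min_eaf=th["min_eaf"])
    out = LocusAnalysis(locus, pair, windows)
    if not windows:
        return out
    window = windows[0]
    wdf = pair.df[pair.df["SNP"].isin(set(window.variant_ids))]
    wpair = dc.HarmonizedPair(
        wdf.reset_index(drop=True), pair.trait_a, pair.trait_b,
        pair.n_flipped, pair.n_dropped_ambiguous,
        pair.n_dropped_irreconcilable)
    out.window_pair = wpair

    res = cl.coloc_abf(wpair, priors=priors)
    ld_sub = locus.ld.subset(wpair.df["SNP"].tolist())
    out.result = res
    out.votes = {
        "abf": res.colocalized(th["regional"], rule="regional"),
        "multi": cl.multi_trait_shared_posterior(
            [res.labf_a, res.labf_b], prior_shared=th["p12"])[0]
        > th["regional"],
        "heuristic": cl.lead_ld_heuristic(wpair, ld_sub, th["lead_ld_r2"]),
    }
    out.colocalized = cl.consensus_call(out.votes)
    if not out.colocalized:
        return out
    out.credible = cl.credible_set(res.snp_pp_h4, level=th["credible_level"],
                                   variant_ids=wpair.df["SNP"].tolist())
    labeled = dc.classify_discordance(wpair, out.credible.member_ids,
                                      p_thresh=th["discord_p"])
    out.signals = dc.clump_signals(labeled, ld_sub, r2_thresh=th["clump_r2"],
                                   locus=window)
    return out


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> RunManifest:
    """Execute all stages and write TSV outputs plus ``manifest.json``."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    th = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    sim_cfg = {**DEFAULT_SIMULATE, **(config.get("simulate") or {})}
    stages = {"finemap": True, "qtl": True, "toa": True, "expression": True,
              **(config.get("stages") or {})}
    out = Path(out_dir or config.get("out_dir", "discoloc_out"))
    for sub in ("windows", "coloc", "signals", "finemap", "qtl", "toa",
                "expression"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    sub_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                 for name, s in zip(
                     ("simulate", "annotations", "qtl", "expression"),
                     ss.spawn(4))}

    loci = sim.simulate_locus_set(
        n_loci=int(sim_cfg["n_loci"]), mix=sim_cfg["mix"],
        seed=sub_seeds["simulate"], p=int(sim_cfg["p"]),
        decay=float(sim_cfg["decay"]), lam=float(sim_cfg["lam"]),
        n_a=int(sim_cfg["n_a"]), n_b=int(sim_cfg["n_b"]))

    priors = (th["p1"], th["p2"], th["p12"])
    window_rows, coloc_rows, signal_rows, finemap_rows = [], [], [], []
    qtl_records: list[qt.QTLColocRecord] = []
    toa_rows = []
    enrich_loci = []
    colocalized = []
    counts = {"loci": len(loci), "windows": 0, "colocalized": 0,
              "credible_variants": 0, "signals": 0, "discordant_signals": 0,
              "concordant_signals": 0}

    rng_ann = np.random.default_rng(sub_seeds["annotations"])
    ann_gamma = {tuple(k) if not isinstance(k, str) else tuple(k.split(":")): v
                 for k, v in (config.get("annotation_gamma")
                              or DEFAULT_ANNOTATION_GAMMA).items()}
    tissues = sorted({t for t, _ in ann_gamma})

    for locus in loci:
        analysis = analyze_locus(locus, th)
        counts["windows"] += len(analysis.windows)
        for w in analysis.windows:
            window_rows.append({"locus": locus.locus_id, "chrom": w.chrom,
                                "start": w.start, "end": w.end,
                                "n_variants": len(w),
                                "seeds": ",".join(w.seed_variants)})
        if analysis.result is None:
            continue
        res = analysis.result
        wpair = analysis.window_pair
        is_coloc = analysis.colocalized
        coloc_rows.append({
            "locus": locus.locus_id, **{k: f"{v:.6g}" for k, v in res.pp.items()},
            "regional": f"{res.regional_prob:.6g}",
            **{f"vote_{k}": v for k, v in analysis.votes.items()},
            "consensus": is_coloc, "truth": locus.truth.hypothesis,
            "truth_discordant": locus.truth.discordant})
        if not is_coloc:
            continue
        counts["colocalized"] += 1
        counts["credible_variants"] += len(analysis.credible)
        signals = analysis.signals
        for sig in signals:
            counts["signals"] += 1
            if sig.label == "discordant":
                counts["discordant_signals"] += 1
            elif sig.label == "concordant":
                counts["concordant_signals"] += 1
            signal_rows.append({
                "locus": locus.locus_id, "lead": sig.lead_id,
                "label": sig.label, "n_members": len(sig.member_ids),
                "z_a": f"{sig.z_a:.6g}", "z_b": f"{sig.z_b:.6g}",
                "members": ",".join(sig.member_ids)})

        # annotation maps + enrichment input over colocalized loci
        amap = sim.simulate_annotations(
            locus.meta, ann_gamma, locus.truth,
            seed=int(rng_ann.integers(2 ** 31)))
        labels = [amap.labels_for(v) for v in wpair.df["SNP"]]
        enrich_loci.append((res.labf_a + res.labf_b, labels))
        colocalized.append((locus, wpair, res, analysis.credible, signals, labels))

    model = None
    if stages["toa"] and enrich_loci:
        model = ta.fit_enrichment(enrich_loci, sorted(ann_gamma), compute_se=False)
        toa_counts: dict[str, int] = {}
        for locus, wpair, res, cs, signals, labels in colocalized:
            ids = wpair.df["SNP"].tolist()
            label_by_id = dict(zip(ids, labels))
            post_by_id = dict(zip(ids, res.snp_pp_h4))
            for sig in signals:
                if sig.label == "unlabeled":
                    continue
                post = [post_by_id[v] for v in sig.member_ids]
                labs = [label_by_id[v] for v in sig.member_ids]
                t_res = ta.toa_scores(f"{locus.locus_id}:{sig.lead_id}", post,
                                      labs, model, tissues,
                                      primary_thresh=th["toa_primary"],
                                      share_margin=th["toa_share"])
                toa_counts[t_res.classification] = (
                    toa_counts.get(t_res.classification, 0) + 1)
                toa_rows.append({
                    "signal": t_res.signal_id, "label": sig.label,
                    "classification": t_res.classification,
                    "shared": "|".join(t_res.shared_tissues),
                    **{f"score_{k}": f"{v:.6g}" for k, v in sorted(t_res.scores.items())}})
        counts["toa_classifications"] = toa_counts

    if stages["finemap"]:
        for locus, wpair, res, cs, signals, labels in colocalized:
            if not any(s.label == "discordant" for s in signals):
                continue
            ld_sub = locus.ld.subset(wpair.df["SNP"].tolist())
            fit = fm.susie_rss(wpair.df["Z_A"].to_numpy(), ld_sub)
            sets = fm.susie_credible_sets(fit, ld_sub)
            for i, s in enumerate(sets):
                finemap_rows.append({
                    "locus": locus.locus_id, "set": i,
                    "lead": s.member_ids[0], "n_members": len(s),
                    "coverage": f"{s.cum_posterior:.4f}",
                    "high_confidence": getattr(s, "high_confidence", False),
                    "members": ",".join(s.member_ids)})
        counts["finemap_sets"] = len(finemap_rows)

    if stages["qtl"]:
        rng_q = np.random.default_rng(sub_seeds["qtl"])
        for locus, wpair, res, cs, signals, labels in colocalized:
            if not any(s.label == "discordant" for s in signals):
                continue
            entries = []
            truth = locus.truth
            shared = sim.ScenarioTruth("H4", truth.causal_a, truth.causal_a,
                                       True, truth.lam)
            _, qtl_stats, _ = sim.simulate_gwas_pair(
                locus.ld, locus.meta, shared, seed=int(rng_q.integers(2 ** 31)))
            qtl_stats.trait_name = f"{locus.locus_id}_geneA_adipose"
            entries.append({"gene": f"{locus.locus_id}_geneA",
                            "tissue": "adipose", "qtl_kind": "eQTL",
                            "stats": qtl_stats})
            null = sim.ScenarioTruth("H0", [], [], True, 0.0)
            _, null_stats, _ = sim.simulate_gwas_pair(
                locus.ld, locus.meta, null, seed=int(rng_q.integers(2 ** 31)))
            null_stats.trait_name = f"{locus.locus_id}_geneB_adipose"
            entries.append({"gene": f"{locus.locus_id}_geneB",
                            "tissue": "adipose", "qtl_kind": "eQTL",
                            "stats": null_stats})
            sub = locus.stats_a.subset(wpair.df["SNP"].tolist())
            qtl_records.extend(qt.run_qtl_integration(
                sub, entries, priors=priors, pph4_thresh=th["qtl_pph4"],
                fdr=th["fdr"]))
        cat_counts: dict[str, int] = {}
        for r in qtl_records:
            cat_counts[r.category or "none"] = cat_counts.get(r.category or "none", 0) + 1
        counts["egenes_by_category"] = cat_counts

    expr_counts = {}
    if stages["expression"]:
        expr_cfg = config.get("expression") or {}
        targets = np.asarray(expr_cfg.get("targets", [[0.5, 0.0], [0.0, 0.0]]),
                             dtype=float)
        expr, pheno = sim.simulate_expression_study(
            int(expr_cfg.get("n_samples", 400)), targets,
            seed=sub_seeds["expression"])
        screen = ex.bicor_screen(expr, pheno, fdr=th["fdr"])
        screen.to_csv(out / "expression" / "bicor_screen.tsv", sep="\t",
                      index=False, float_format="%.6g")
        tc_cfg = config.get("timecourse") or {}
        frame, design, truth_dyn = sim.simulate_timecourse(
            int(tc_cfg.get("n_genes", 50)),
            float(tc_cfg.get("dynamic_fraction", 0.2)),
            tc_cfg.get("timepoints", [0, 2, 4, 8, 12, 16]),
            effect=float(tc_cfg.get("effect", 0.5)),
            seed=sub_seeds["expression"] + 1)
        lrt = ex.lrt_screen(frame, design["time"].to_numpy())
        lrt.to_csv(out / "expression" / "lrt_dynamic.tsv", sep="\t",
                   index=False, float_format="%.6g")
        expr_counts = {"bicor_significant": int(screen["significant"].sum()),
                       "dynamic_genes": int(lrt["dynamic"].sum())}
        counts["expression"] = expr_counts

    # ---- outputs ---------------------------------------------------------
    def _write(rows, name, sub):
        pd.DataFrame(rows).to_csv(out / sub / name, sep="\t", index=False)

    _write(window_rows, "windows.tsv", "windows")
    _write(coloc_rows, "coloc.tsv", "coloc")
    _write(signal_rows, "signals.tsv", "signals")
    _write(finemap_rows, "credible_sets.tsv", "finemap")
    _write(toa_rows, "toa_scores.tsv", "toa")
    if qtl_records:
        qt.egene_catalog(qtl_records).to_csv(out / "qtl" / "egene_catalog.tsv",
                                             sep="\t", index=False,
                                             float_format="%.6g")
        pd.DataFrame([asdict(r) for r in qtl_records]).to_csv(
            out / "qtl" / "qtl_coloc.tsv", sep="\t", index=False,
            float_format="%.6g")
    else:
        _write([], "qtl_coloc.tsv", "qtl")

    manifest = RunManifest(seed=seed, version="0.1.0",
                           config=_stringify_keys(config),
                           counts=counts, parameters=th)
    manifest.validate()
    manifest.write(out / "manifest.json")
    log.info("pipeline complete: %s", counts)
    return manifest
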