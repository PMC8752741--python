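"""End-to-end orchestration: simulate → DEG → DDEG → network → CRE → peaks → GRN.

``run_pipeline`` executes every stage in dependency order from one
configuration and returns a machine-readable report (JSON-serializable
dict).  A single global seed fans out to per-stage generators through
``numpy.random.SeedSequence``, so identical configurations give
byte-identical reports.  When ground truth is available (always, for the
synthetic generator) the report carries a truth-comparison block: planted
module recovery (adjusted Rand index), DDEG sensitivity, planted-peak
recovery, and hub recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import cistrome as cistrome_mod
from . import coexpression, ddeg as ddeg_mod, deg as deg_mod
from . import integration as integration_mod
from . import peaks as peaks_mod, simulate
from .exceptions import ParameterError
from .io import write_edge_list

log = logging.getLogger("uprnet")


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's printed values."""

    seed: int = 0
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    deg: deg_mod.DEGThresholds = field(default_factory=deg_mod.DEGThresholds)
    ddeg_alpha: float = 0.01
    network: coexpression.NetworkParams = field(default_factory=coexpression.NetworkParams)
    cistrome: cistrome_mod.CistromeParams = field(default_factory=cistrome_mod.CistromeParams)
    peaks: peaks_mod.PeakFilterParams = field(default_factory=peaks_mod.PeakFilterParams)
    integration: integration_mod.IntegrationParams = field(default_factory=integration_mod.IntegrationParams)
    enrichment: integration_mod.EnrichmentParams = field(default_factory=integration_mod.EnrichmentParams)

    def __post_init__(self):
        # the global seed drives the simulation unless one was set explicitly
        if self.simulation.seed != self.seed and self.simulation.seed == 0:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        blocks = {
            "simulation": simulate.SimulationConfig,
            "deg": deg_mod.DEGThresholds,
            "network": coexpression.NetworkParams,
            "cistrome": cistrome_mod.CistromeParams,
            "peaks": peaks_mod.PeakFilterParams,
            "integration": integration_mod.IntegrationParams,
            "enrichment": integration_mod.EnrichmentParams,
        }
        for key, value in raw.items():
            if key in ("seed", "ddeg_alpha"):
                kwargs[key] = value
            elif key in blocks:
                klass = blocks[key]
                names = {f.name for f in dataclasses.fields(klass)}
                unknown = set(value) - names
                if unknown:
                    raise ParameterError(f"unknown keys in {key!r} block: {sorted(unknown)}")
                if key == "simulation":
                    value = _coerce_simulation(value)
                kwargs[key] = klass(**value)
            else:
                raise ParameterError(f"unknown configuration key {key!r}")
        return cls(**kwargs)


def _coerce_simulation(value: dict) -> dict:
    value = dict(value)
    if "module_spec" in value:
        value["module_spec"] = tuple(simulate.ModuleSpec(**m) for m in value["module_spec"])
    if "ddeg_spec" in value:
        value["ddeg_spec"] = tuple(simulate.DdegSpec(**d) for d in value["ddeg_spec"])
    if "peak_spec" in value:
        value["peak_spec"] = {tf: simulate.PeakSpec(**p) for tf, p in value["peak_spec"].items()}
    if "cre_plant_rates" in value:
        value["cre_plant_rates"] = {k: tuple(v) for k, v in value["cre_plant_rates"].items()}
    for key in ("genotypes", "timepoints"):
        if key in value:
            value[key] = tuple(value[key])
    return value


def _round(obj, digits: int = 10):
    """Round floats recursively so serialized reports are byte-stable."""
    if isinstance(obj, float):
        if math.isinf(obj) or math.isnan(obj):
            return repr(obj)
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {str(k): _round(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        items = sorted(obj) if isinstance(obj, set) else list(obj)
        return [_round(v, digits) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round(float(obj), digits)
    return obj


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on synthetic inputs and return the report dict."""
    report: dict = {"seed": config.seed}
    sim = config.simulation
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: simulate ------------------------------------------------
    log.info("stage simulate: %d genes", sim.n_genes)
    counts, sheet, truth_counts = simulate.simulate_counts(sim)
    annotation, promoters, genome, truth_genome = simulate.simulate_genome(sim)
    peaksets, truth_peaks = simulate.simulate_peaks(sim, annotation, truth=truth_genome)
    truth = simulate.merge_truth(truth_counts, truth_peaks)
    report["simulate"] = {
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_planted_deg": len(truth.deg_genes),
        "n_planted_ddeg": {k: len(v) for k, v in truth.ddeg_genes.items()},
        "n_peak_files": sum(len(v) for v in peaksets.values()),
    }

    # --- stage 2: DEG ------------------------------------------------------
    log.info("stage deg")
    results = deg_mod.run_all_contrasts(counts, sheet, config.deg)
    degset = deg_mod.call_degs(results, config.deg)
    wt = sim.genotypes[0]
    fisher = {}
    n_tested = {
        (g, t): int(((results["genotype"] == g) & (results["timepoint"] == t)
                     & results["tested"]).sum())
        for g, t in degset.per_contrast
    }
    for mutant in sim.genotypes[1:]:
        for tp in sim.timepoints:
            a = len(degset.per_contrast.get((wt, tp), set()))
            b = len(degset.per_contrast.get((mutant, tp), set()))
            fisher[f"{wt}_vs_{mutant}@{tp}h"] = deg_mod.fisher_count_compare(
                a, n_tested.get((wt, tp), a), b, n_tested.get((mutant, tp), b))
    report["deg"] = {
        "per_contrast": {f"{g}@{t}h": len(s) for (g, t), s in degset.per_contrast.items()},
        "union": len(degset.union),
        "fisher_count_p": fisher,
    }

    # --- stage 3: DDEG ------------------------------------------------------
    log.info("stage ddeg")
    rlfc = ddeg_mod.replicate_lfc(counts, sheet, config.deg.pseudocount)
    ddegset = ddeg_mod.call_ddegs(degset.union, rlfc, alpha=config.ddeg_alpha)
    report["ddeg"] = {
        "per_comparison": {f"{p}@{t}h": n for (p, t), n in ddegset.comparison_counts.items()},
        "per_pair_union": {p: len(s) for p, s in ddegset.per_pair_union.items()},
        "median_comparison_count": ddegset.median_comparison_count,
    }

    # --- stage 4: coexpression network -------------------------------------
    log.info("stage network")
    Xnet, truth_net = simulate.simulate_lfc_matrix(sim)
    adj = coexpression.signed_adjacency(Xnet, config.network)
    tom = coexpression.tom_similarity(adj)
    modules, _ = coexpression.detect_modules(tom, config.network)
    modules = coexpression.merge_modules(Xnet, modules, config.network.merge_cut_height)
    eigengenes, varexp = coexpression.module_eigengene(Xnet, modules)
    truth_labels = [truth_net.module_of_gene[g] for g in Xnet.index]
    det_labels = [modules[g] for g in Xnet.index]
    ari = float(adjusted_rand_score(truth_labels, det_labels))
    module_sizes = modules[modules != coexpression.UNASSIGNED].value_counts().to_dict()
    report["network"] = {
        "n_modules": len(module_sizes),
        "module_sizes": {str(k): int(v) for k, v in module_sizes.items()},
        "variance_explained": varexp,
    }

    # --- stage 5: CRE enrichment on DDEG promoters --------------------------
    log.info("stage cistrome")
    all_ddeg = set().union(*ddegset.per_pair_union.values()) if ddegset.per_pair_union else set()
    target_prom = {g: promoters[g] for g in sorted(all_ddeg) if g in promoters}
    rng = sim.rng(8)
    deg_background = {g: promoters[g] for g in sorted(degset.union)}
    control_prom = cistrome_mod.draw_control_set(
        deg_background, set(target_prom), config.cistrome.control_size, rng)
    cre_block = {}
    patterns = cistrome_mod.builtin_patterns()
    if target_prom:
        for name, pat in patterns.items():
            res = cistrome_mod.set_enrichment(target_prom, control_prom, pat, config.cistrome)
            cre_block[name] = {
                "target_with": res.target_with, "target_total": res.target_total,
                "control_with": res.control_with, "control_total": res.control_total,
                "p": res.p,
            }
    report["cre_enrichment"] = cre_block

    # --- stage 6: peak filtering --------------------------------------------
    log.info("stage peaks")
    bound_sets: dict[str, set] = {}
    peaks_block = {}
    merged_by_tf = {}
    for tf, sets in peaksets.items():
        by_key = {}
        for ps in sets:
            by_key.setdefault((ps.condition, ps.timepoint), []).append(ps)
        retained_tps = []
        for tp in sim.timepoints:
            tm_rep = peaks_mod.reproducible_peaks(*by_key[("Tm", tp)], config.peaks)
            mock_rep = peaks_mod.reproducible_peaks(*by_key[("mock", tp)], config.peaks)
            retained, eliminated = peaks_mod.upr_specific_filter(tm_rep, mock_rep, config.peaks)
            retained_tps.append(retained)
        merged = peaks_mod.merge_across_timepoints(retained_tps)
        merged_by_tf[tf] = merged
        _, _, bound, intergenic = peaks_mod.assign_peaks_to_genes(
            merged, annotation, config.peaks)
        bound_sets[tf] = bound
        loc = peaks_mod.location_summary(merged, annotation, config.peaks.promoter_window)
        retained_ids = merged.ids
        spec_ids = truth.specific_peaks.get(tf, set())
        const_ids = truth.constitutive_peaks.get(tf, set())
        peaks_block[tf] = {
            "retained": len(merged),
            "bound_genes": len(bound),
            "intergenic": len(intergenic),
            "location": {k: int(v) for k, v in loc.items()},
            "specific_recovered": len(retained_ids & spec_ids),
            "specific_planted": len(spec_ids),
            "constitutive_retained": len(retained_ids & const_ids),
        }
    tfs = sorted(bound_sets)
    overlap_block = {}
    if len(tfs) == 2:
        universe = set(annotation["gene_id"])
        p, logp = integration_mod.overlap_significance(bound_sets[tfs[0]], bound_sets[tfs[1]], universe)
        overlap_block = {
            "bound_overlap": len(bound_sets[tfs[0]] & bound_sets[tfs[1]]),
            "p": p, "log10_p": logp / math.log(10.0),
        }
    report["peaks"] = peaks_block
    report["bound_overlap"] = overlap_block

    # --- stage 7: summit centrality -----------------------------------------
    log.info("stage centrality")
    flank = config.cistrome.summit_flank
    centrality_block = {}
    for tf, merged in merged_by_tf.items():
        windows = []
        for r in merged.peaks.itertuples(index=False):
            seq = genome[r.chrom][r.summit - flank:r.summit + flank]
            if len(seq) == 2 * flank:
                windows.append(seq)
        res = cistrome_mod.positional_centrality(windows, patterns["ERSE-I"], config.cistrome)
        centrality_block[tf] = {
            "n_windows": res.n_windows, "n_with_match": res.n_with_match,
            "n_central": res.n_central, "p0": res.p0, "p": res.p, "status": res.status,
        }
    report["centrality"] = centrality_block

    # --- stage 8: GRN integration -------------------------------------------
    log.info("stage integrate")
    grn_block = {}
    # focus module = detected module with the most TF-bound genes, over the
    # study rLFC matrix restricted to union DEGs
    study_X = rlfc.loc[sorted(degset.union)]
    study_X.columns = ["{}_{}h_r{}".format(*c) for c in study_X.columns]
    study_adj = coexpression.signed_adjacency(study_X, config.network)
    study_tom = coexpression.tom_similarity(study_adj)
    study_modules, _ = coexpression.detect_modules(study_tom, config.network)
    study_modules = coexpression.merge_modules(study_X, study_modules,
                                               config.network.merge_cut_height)
    all_bound = set().union(*bound_sets.values()) if bound_sets else set()
    mods = sorted(set(study_modules) - {coexpression.UNASSIGNED})
    report["network"]["study_modules"] = {
        m: int((study_modules == m).sum()) for m in mods}
    if mods:
        focus = max(mods, key=lambda m: (
            len(set(study_modules[study_modules == m].index) & all_bound), m))
        edges, nodes = coexpression.export_network(
            study_tom, study_modules, config.network.edge_weight_cutoff, module=focus)
        grn = integration_mod.build_grn(edges, nodes, bound_sets, module=focus)
        subs = integration_mod.subnetworks(grn)
        hubs = integration_mod.rank_hubs(grn, config.integration)
        term_map = simulate.simulate_term_map(sim, truth)
        universe = set(annotation["gene_id"])
        enrich = integration_mod.hypergeometric_enrichment(
            set(nodes), term_map, universe, config.enrichment)
        hub_rows = hubs[hubs["hub_flag"]]
        grn_block = {
            "focus_module": focus,
            "n_nodes": len(nodes),
            "n_edges": len(edges),
            "subnetwork_sizes": {k: len(v) for k, v in subs.items()},
            "bound_in_module": {tf: len(set(nodes) & s) for tf, s in bound_sets.items()},
            "hubs": [
                {"subnetwork": r.subnetwork, "gene": r.gene, "degree": int(r.degree),
                 "percentile": float(r.percentile)}
                for r in hub_rows.itertuples(index=False)
            ],
            "enriched_terms": sorted(enrich[enrich["enriched"]]["term"].tolist()),
        }
        if outdir is not None:
            write_edge_list(grn, outdir / "grn_edges.tsv")
    report["grn"] = grn_block

    # --- truth comparison ----------------------------------------------------
    hub_X, hub_gene = simulate.simulate_hub_scenario(seed=sim.seed)
    hub_adj = coexpression.signed_adjacency(hub_X, config.network)
    hub_tom = coexpression.tom_similarity(hub_adj)
    deg_counts = (hub_tom.to_numpy() >= config.network.edge_weight_cutoff).sum(axis=1) - 1
    order = np.argsort(-deg_counts, kind="stable")
    rank = int(np.where(hub_X.index[order] == hub_gene)[0][0]) + 1
    hub_top10 = rank <= math.ceil(0.10 * len(hub_X))

    sensitivity = {}
    for pair, planted in truth.ddeg_genes.items():
        called = ddegset.per_pair_union.get(pair, set())
        sensitivity[pair] = len(called & planted) / len(planted) if planted else float("nan")
    spec_total = sum(len(v) for v in truth.specific_peaks.values())
    spec_found = sum(peaks_block[tf]["specific_recovered"] for tf in peaks_block)
    const_kept = sum(peaks_block[tf]["constitutive_retained"] for tf in peaks_block)
    report["truth_comparison"] = {
        "module_ari": ari,
        "ddeg_sensitivity": sensitivity,
        "peak_recovery": spec_found / spec_total if spec_total else float("nan"),
        "constitutive_retained": const_kept,
        "hub_rank": rank,
        "hub_in_top10pct": bool(hub_top10),
    }

    report = _round(report)
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        simulate.write_inputs(sim, outdir / "inputs")
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True)
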