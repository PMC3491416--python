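"""End-to-end pipeline: simulate -> peaks -> ΔDNase -> expression ->
association -> motif scan -> footprints, with all outputs on disk.

Every stage takes its tunables from :class:`RunConfig`; a run is fully
reproducible from the config alone (all randomness derives from
``config.seed``), and result files are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association, delta_dnase, expression, footprint, motif, peaks
from .core_io import (
    GenomicInterval,
    PWM,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gene_models,
)
from .synthetic_data import (
    INDUCED,
    UNTREATED,
    SimScenario,
    build_scenario,
    simulate_all_cuts,
    simulate_expression,
    simulate_sequence,
)


def ar_like_pwm() -> PWM:
    """Synthetic stand-in for a nuclear-receptor dimer PWM.

    A 15-bp palindromic hormone-response-element-like motif: two 6-bp
    half-sites (AGAACA / TGTTCT) separated by a degenerate 3-bp spacer.
    Constructed, not derived from any motif database.
    """
    strong, weak = 0.85, 0.05
    cols = []
    for base in "AGAACA":
        col = np.full(4, weak)
        col["ACGT".index(base)] = strong
        cols.append(col)
    for _ in range(3):
        cols.append(np.full(4, 0.25))
    for base in "TGTTCT":
        col = np.full(4, weak)
        col["ACGT".index(base)] = strong
        cols.append(col)
    return PWM(np.array(cols).T, name="synthetic_hre_dimer")


def dedupe_matches(
    matches: list[GenomicInterval], min_dist: int = 15
) -> list[GenomicInterval]:
    """Greedily keep the strongest match per locus: matches whose centers
    lie within ``min_dist`` bp of an already-kept stronger match drop."""
    kept: list[GenomicInterval] = []
    centers: list[int] = []
    for m in sorted(matches, key=lambda m: (-(m.score or 0), m.chrom, m.start)):
        c = m.midpoint
        if any(
            k.chrom == m.chrom and abs(c - kc) < min_dist
            for k, kc in zip(kept, centers)
        ):
            continue
        kept.append(m)
        centers.append(c)
    return sorted(kept, key=lambda m: (m.chrom, m.start))


@dataclass
class RunConfig:
    """All pipeline tunables (defaults follow the analysis described in
    the package docs)."""

    outdir: str = "deltadnase_run"
    seed: int = 1
    # peak calling
    bandwidth: float = 60.0
    gamma_p: float = 0.05
    min_gap: int = 50
    # window tiling / differential testing
    window: int = 300
    step: int = 150
    edge_frac: float = 0.10
    min_sum: int = 5
    strict_fdr: float = 0.05
    loose_p: float = 0.05
    # expression / association
    de_fdr: float = 0.05
    promoter: int = 2000
    assoc_window: int = 20_000
    n_perm_forward: int = 100_000
    n_perm_reverse: int = 1000
    # motif / footprint
    pwm_percentile: float = 90.0
    half: int = 15
    flank: int = 100
    k: int = 3
    runs: int = 100
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    # synthetic scenario
    scenario_kwargs: dict = dataclasses.field(default_factory=dict)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, scenario: SimScenario | None = None) -> dict:
    """Execute the full pipeline and write the result bundle to
    ``config.outdir``; returns the machine-readable summary dict."""
    os.makedirs(config.outdir, exist_ok=True)
    logf = open(os.path.join(config.outdir, "run_log.txt"), "w")
    summary: dict = {"seed": config.seed, "parameters": _params(config)}

    def log(msg: str) -> None:
        logf.write(msg + "\n")

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    try:
        stage = "simulate"
        if scenario is None:
            scenario = build_scenario(config.seed, **config.scenario_kwargs)
        profiles = simulate_all_cuts(scenario)
        pwm = ar_like_pwm()
        sequences = simulate_sequence(scenario, pwm)
        expr_counts, expr_conditions = simulate_expression(scenario)
        for cond, plist in profiles.items():
            for i, p in enumerate(plist):
                write_bedgraph(out(f"cuts_{cond}_{i}.bedgraph"), p)
        write_bed(out("truth_dhs.bed"), scenario.dhs)
        write_bed(out("truth_increase.bed"), scenario.planted_regions)
        write_bed(
            out("truth_motif_sites.bed"),
            [s.interval for s in scenario.motif_sites],
        )
        write_gene_models(out("genes.tsv"), scenario.genes)
        write_fasta(out("genome.fa"), sequences)
        expr_counts.to_csv(out("expression_counts.tsv"), sep="\t")
        log(f"simulate: seed={config.seed} "
            f"genome={scenario.chrom_sizes} dhs={len(scenario.dhs)}")

        stage = "callpeaks"
        peaksets = {}
        for cond, plist in profiles.items():
            pooled = peaks.pooled_profile(plist)
            track = peaks.kde_signal(pooled, config.bandwidth)
            thr = peaks.gamma_threshold(track, config.gamma_p)
            ps = peaks.call_peaks(track, thr, config.min_gap)
            peaksets[cond] = ps
            write_bed(out(f"peaks_{cond}.bed"), list(ps))
            summary[f"n_peaks_{cond}"] = len(ps)
            log(f"callpeaks[{cond}]: threshold={thr:.6g} peaks={len(ps)}")
        ov = peaks.overlap_fraction(peaksets[UNTREATED], peaksets[INDUCED])
        summary["peak_overlap"] = {
            "frac_untreated": ov.frac_a,
            "frac_induced": ov.frac_b,
        }

        stage = "delta"
        union = delta_dnase.union_regions(
            peaksets[UNTREATED], peaksets[INDUCED]
        )
        windows = delta_dnase.tile_regions(
            union, config.window, config.step, config.edge_frac,
            scenario.chrom_sizes,
        )
        all_profiles = profiles[UNTREATED] + profiles[INDUCED]
        matrix = delta_dnase.count_and_filter(
            windows, all_profiles, config.min_sum
        )
        diff = delta_dnase.nb_exact_test(matrix)
        sets = delta_dnase.classify_and_merge(
            diff, config.strict_fdr, config.loose_p
        )
        scores = delta_dnase.normalized_differential_score(
            union, profiles[UNTREATED], profiles[INDUCED]
        )
        write_bed(out("union_dhs.bed"), union)
        pd.DataFrame(
            {
                "chrom": [r.chrom for r in union],
                "start": [r.start for r in union],
                "end": [r.end for r in union],
                "differential_tag_score": scores,
            }
        ).to_csv(out("union_differential_scores.tsv"), sep="\t", index=False)
        _write_diff(out("window_tests.tsv"), diff, matrix)
        for name in (
            "strict_increase", "loose_increase",
            "strict_decrease", "loose_decrease",
        ):
            regs = getattr(sets, name)
            write_bed(out(f"delta_{name}.bed"), regs)
            summary[f"n_{name}"] = len(regs)
        log(
            "delta: windows=%d tested=%d strict_inc=%d loose_inc=%d "
            "strict_dec=%d loose_dec=%d"
            % (
                len(windows), len(matrix.windows),
                len(sets.strict_increase), len(sets.loose_increase),
                len(sets.strict_decrease), len(sets.loose_decrease),
            )
        )

        stage = "express"
        de = expression.de_genes(expr_counts, expr_conditions, config.de_fdr)
        de.table.to_csv(out("de_genes.tsv"), sep="\t", index=False)
        summary["n_de_up"] = len(de.upregulated)
        summary["n_de_down"] = len(de.downregulated)
        log(f"express: up={len(de.upregulated)} down={len(de.downregulated)}")

        stage = "associate"
        universe = {g.gene_id for g in scenario.genes}
        increases = sets.loose_increase
        cat = association.annotate_regions(
            increases, scenario.genes, config.promoter
        )
        summary["increase_categories"] = cat.fractions
        if increases and de.upregulated:
            near = association.nearest_gene(increases, scenario.genes)
            region_genes = {g.gene_id for g in near.values()}
            fwd = association.permutation_enrichment(
                region_genes, set(de.upregulated), universe,
                config.n_perm_forward, seed=config.seed + 101,
            )
            rev = association.reverse_association(
                set(de.upregulated), increases, scenario.genes,
                config.assoc_window, config.n_perm_reverse,
                seed=config.seed + 102,
            )
            summary["association"] = {
                "forward_observed": fwd.observed,
                "forward_p_enrich": fwd.p_enrich,
                "forward_p_deplete": fwd.p_deplete,
                "reverse_observed": rev.observed,
                "reverse_p_enrich": rev.p_enrich,
                "reverse_p_deplete": rev.p_deplete,
            }
            log(
                f"associate: forward p={fwd.p_enrich:.3g} "
                f"reverse p={rev.p_enrich:.3g}"
            )

        stage = "scan"
        chrom = next(iter(scenario.chrom_sizes))
        matches = motif.scan_sequence(
            sequences[chrom], pwm, chrom, config.pwm_percentile,
            regions=scenario.dhs,
        )
        matches = dedupe_matches(matches, min_dist=pwm.width)
        write_bed(out("motif_matches.bed"), matches)
        truth_sites = [s.interval for s in scenario.motif_sites]
        rec = peaks.overlap_fraction(truth_sites, matches)
        summary["motif_site_recovery"] = rec.frac_a
        summary["n_motif_matches"] = len(matches)
        # strong matches (>= half the best score) give a sparse set suited
        # to region-level enrichment contrasts
        max_score = max((m.score or 0.0) for m in matches) if matches else 0.0
        strong = [m for m in matches if (m.score or 0.0) >= 0.5 * max_score]
        summary["n_strong_matches"] = len(strong)
        hosts = [
            d for d in scenario.dhs
            if any(d.overlaps(t) for t in truth_sites)
        ]
        plain = [
            d for d in scenario.dhs
            if not any(d.overlaps(t) for t in truth_sites)
        ]
        if hosts and plain:
            frac_host = peaks.overlap_fraction(hosts, strong).frac_a
            frac_plain = peaks.overlap_fraction(plain, strong).frac_a
            summary["strong_match_frac_host_dhs"] = frac_host
            summary["strong_match_frac_other_dhs"] = frac_plain
            if frac_plain > 0:
                summary["relative_enrichment_host_vs_other_dhs"] = (
                    motif.relative_enrichment(strong, hosts, plain)
                )
        log(f"scan: matches={len(matches)} recovery={rec.frac_a:.3f}")

        stage = "footprint"
        site_matches = [
            m for m in matches
            if any(m.overlaps(t) for t in truth_sites)
        ]
        fp_summary = {}
        stability = {}
        for cond in (UNTREATED, INDUCED):
            pooled = peaks.pooled_profile(profiles[cond])
            mat = footprint.footprint_matrix(pooled, site_matches, config.half)
            agg = footprint.aggregate_profile(pooled, site_matches, config.flank)
            np.savetxt(out(f"aggregate_{cond}.tsv"), agg[None], fmt="%d",
                       delimiter="\t")
            res = footprint.kmeans_stability(
                mat, config.k, config.runs, seed=config.seed + 7
            )
            stability[cond] = res
            fp_summary[cond] = {
                "n_sites": len(mat),
                "median_matched_correlation": res.median,
            }
        comp = footprint.compare_stability(
            stability[INDUCED], stability[UNTREATED]
        )
        sel = footprint.select_k(
            footprint.footprint_matrix(
                peaks.pooled_profile(profiles[INDUCED]), site_matches,
                config.half,
            ),
            list(config.k_range), config.runs, seed=config.seed + 8,
        )
        fp_summary["mannwhitney_p"] = comp.pvalue
        fp_summary["higher_condition"] = (
            INDUCED if comp.higher == "a"
            else UNTREATED if comp.higher == "b" else "tie"
        )
        fp_summary["selected_k"] = sel["recommended"]
        fp_summary["k_medians"] = {str(k): v for k, v in sel["medians"].items()}
        summary["footprint"] = fp_summary
        log(
            f"footprint: MW p={comp.pvalue:.3g} "
            f"higher={fp_summary['higher_condition']} k={sel['recommended']}"
        )
    except Exception as exc:  # noqa: BLE001
        logf.close()
        if isinstance(exc, StageFailure):
            raise
        raise StageFailure(stage, exc) from exc

    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log("done")
    logf.close()
    return summary


def _params(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["k_range"] = list(d["k_range"])
    return d


def _write_diff(path: str, diff, matrix) -> None:
    rows = {
        "chrom": [w.interval.chrom for w in diff.windows],
        "start": [w.interval.start for w in diff.windows],
        "end": [w.interval.end for w in diff.windows],
        "parent_region": [w.parent for w in diff.windows],
        "log2fc": diff.log2fc,
        "pvalue": diff.pvalue,
        "fdr": diff.fdr,
    }
    for j, name in enumerate(matrix.replicate_names):
        rows[f"count_{name}"] = matrix.counts[:, j]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
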