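"""Synthetic DNase-seq / mRNA-seq scenario generator.

Emulates the data structure the pipeline assumes: replicate per-base cut
profiles with background and DHS-elevated negative-binomial rates, planted
condition-specific accessibility increases, planted motif instances carrying
one of three footprint protection shapes (left half-site, right half-site,
full dimer site with a central spike at the degenerate 3-bp spacer), and
gene-level expression counts in which differentially expressed genes sit
near planted accessibility increases, so the downstream association tests
have a true alternative by construction.

Protein binding in vivo protects the motif core from DNase I cleavage while
accessibility in the immediately surrounding DNA is elevated; templates
therefore combine a per-bp core protection multiplier in [0, 1] with a
flank multiplier slightly above 1 applied over the surrounding 100 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import CutProfile, GeneModel, GenomicInterval, PWM

UNTREATED = "untreated"
INDUCED = "induced"

FOOTPRINT_CORE = 31  # bp: motif center +/- 15


@dataclass(frozen=True)
class FootprintTemplate:
    """Per-bp protection multipliers over the 31-bp footprint core.

    ``values[i]`` scales the cut rate at core position i (0-based, motif
    center at index 15); ``flank`` scales the rate over the surrounding
    ``flank_bp`` on each side of the core.
    """

    name: str
    values: np.ndarray
    flank: float = 1.16
    flank_bp: int = 100

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (FOOTPRINT_CORE,):
            raise ValueError(f"template must have {FOOTPRINT_CORE} values")
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("core protection multipliers must lie in [0, 1]")
        object.__setattr__(self, "values", vals)


def _template(name: str, protected: list[tuple[int, int]],
              protection: float = 0.15) -> FootprintTemplate:
    vals = np.ones(FOOTPRINT_CORE)
    for s, e in protected:
        vals[s:e] = protection
    return FootprintTemplate(name, vals)


def default_templates() -> dict[str, FootprintTemplate]:
    """The three canonical protection shapes.

    ``left_half`` protects core bp 1-14, ``right_half`` its mirror image,
    ``full_dimer`` both half-sites with the central 3-bp spacer exposed.
    """
    return {
        "left_half": _template("left_half", [(0, 14)]),
        "right_half": _template("right_half", [(17, 31)]),
        "full_dimer": _template("full_dimer", [(0, 14), (17, 31)]),
    }


@dataclass(frozen=True)
class MotifSite:
    """A planted motif instance inside a DHS region."""

    interval: GenomicInterval
    template: str

    @property
    def center(self) -> int:
        return self.interval.midpoint


@dataclass
class SimScenario:
    """Complete description of one simulated experiment."""

    chrom_sizes: dict[str, int]
    lambda_bg: float
    dhs: list[GenomicInterval]
    dhs_multiplier: dict[int, float]          # index into dhs -> rate multiplier
    planted_increase: list[int]               # indices into dhs
    fold_change: float
    motif_sites: list[MotifSite]
    templates: dict[str, FootprintTemplate]
    footprint_conditions: tuple[str, ...]
    genes: list[GeneModel]
    de_genes: dict[str, float]                # gene id -> induced fold change
    gene_level: dict[str, float]              # gene id -> baseline mean count
    n_replicates: dict[str, int]
    depth_factor: dict[tuple[str, int], float]
    dispersion: float
    expr_dispersion: float
    seed: int

    def __post_init__(self) -> None:
        if self.lambda_bg <= 0:
            raise ValueError("lambda_bg must be > 0")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for iv in self.dhs:
            if iv.end > self.chrom_sizes[iv.chrom]:
                raise ValueError(f"DHS {iv} outside genome")
        incs = [self.dhs[i] for i in self.planted_increase]
        for a, b in zip(sorted(incs), sorted(incs)[1:]):
            if a.overlaps(b):
                raise ValueError("planted regions overlap")
        dhs_sorted = sorted(self.dhs)
        for site in self.motif_sites:
            if not any(
                d.start <= site.interval.start and site.interval.end <= d.end
                for d in dhs_sorted
                if d.chrom == site.interval.chrom
            ):
                raise ValueError(f"motif site {site.interval} outside DHS")

    @property
    def planted_regions(self) -> list[GenomicInterval]:
        return [self.dhs[i] for i in self.planted_increase]

    def rng(self, *stream: int | str) -> np.random.Generator:
        key = tuple(
            s if isinstance(s, int) else abs(hash(s)) % (2**31)
            for s in stream
        )
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=key)
        )


def build_scenario(
    seed: int,
    genome_length: int = 2_000_000,
    chrom: str = "chr1",
    lambda_bg: float = 0.01,
    n_dhs: int = 500,
    dhs_multiplier: float = 12.0,
    site_dhs_multiplier: float = 20.0,
    n_increase: int = 50,
    fold_change: float = 3.0,
    n_motif_sites: int = 600,
    motif_width: int = 15,
    plain_width: tuple[int, int] = (250, 450),
    host_width: tuple[int, int] = (500, 700),
    n_genes: int = 200,
    n_de: int = 40,
    de_fold: float = 4.0,
    n_untreated: int = 3,
    n_induced: int = 3,
    dispersion: float = 0.05,
    expr_dispersion: float = 0.1,
    footprint_conditions: tuple[str, ...] = (INDUCED,),
    depth_sd: float = 0.15,
) -> SimScenario:
    """Deterministically lay out a scenario from a seed.

    Defaults: 2-Mb genome, 500 DHS regions, 50 of them planted with a
    3-fold accessibility increase upon induction, 600 motif sites (200 per
    footprint template) hosted two per strongly hypersensitive DHS, and 200
    genes of which 40 are 4-fold upregulated with TSSs placed next to
    planted increases.
    """
    templates = default_templates()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    n_hosts = -(-n_motif_sites // 2) if n_motif_sites else 0
    if n_dhs and n_dhs < n_increase + n_hosts:
        raise ValueError("too few DHS for planted regions and motif hosts")

    # one DHS per equal-width slot keeps regions non-overlapping by design
    dhs: list[GenomicInterval] = []
    multipliers: dict[int, float] = {}
    if n_dhs:
        slot = genome_length // n_dhs
        if slot < 1200:
            raise ValueError("genome too small for requested DHS count")
        roles = ["plain"] * n_dhs
        order = rng.permutation(n_dhs)
        for i in order[:n_increase]:
            roles[i] = "increase"
        for i in order[n_increase : n_increase + n_hosts]:
            roles[i] = "host"
        for i in range(n_dhs):
            lo = i * slot + 300
            width = (
                int(rng.integers(*host_width))
                if roles[i] == "host"
                else int(rng.integers(*plain_width))
            )
            start = int(rng.integers(lo, lo + slot - width - 600))
            dhs.append(GenomicInterval(chrom, start, start + width))
            multipliers[i] = (
                site_dhs_multiplier if roles[i] == "host" else dhs_multiplier
            )
        planted = [i for i in range(n_dhs) if roles[i] == "increase"]
        hosts = [i for i in range(n_dhs) if roles[i] == "host"]
    else:
        planted, hosts = [], []

    # motif sites: two per host DHS, centers 250 bp apart, random strand
    template_names = sorted(templates)
    sites: list[MotifSite] = []
    assignment = [
        template_names[j % len(template_names)] for j in range(n_motif_sites)
    ]
    site_slots: list[int] = []
    for h in hosts:
        site_slots += [h, h]
    for j in range(n_motif_sites):
        d = dhs[site_slots[j]]
        center = d.midpoint + (-125 if j % 2 == 0 else 125)
        half = motif_width // 2
        strand = "+" if rng.random() < 0.5 else "-"
        sites.append(
            MotifSite(
                GenomicInterval(
                    chrom, center - half, center - half + motif_width, strand
                ),
                assignment[j],
            )
        )

    genes, de, levels = _layout_genes(
        rng, chrom, genome_length, n_genes, n_de, de_fold,
        [dhs[i] for i in planted],
    )

    depth = {}
    for cond, n in ((UNTREATED, n_untreated), (INDUCED, n_induced)):
        for r in range(n):
            depth[(cond, r)] = float(np.exp(rng.normal(0.0, depth_sd)))

    return SimScenario(
        chrom_sizes={chrom: genome_length},
        lambda_bg=lambda_bg,
        dhs=dhs,
        dhs_multiplier=multipliers,
        planted_increase=planted,
        fold_change=fold_change,
        motif_sites=sites,
        templates=templates,
        footprint_conditions=footprint_conditions,
        genes=genes,
        de_genes=de,
        gene_level=levels,
        n_replicates={UNTREATED: n_untreated, INDUCED: n_induced},
        depth_factor=depth,
        dispersion=dispersion,
        expr_dispersion=expr_dispersion,
        seed=seed,
    )


def _layout_genes(
    rng: np.random.Generator,
    chrom: str,
    genome_length: int,
    n_genes: int,
    n_de: int,
    de_fold: float,
    increases: list[GenomicInterval],
) -> tuple[list[GeneModel], dict[str, float], dict[str, float]]:
    """DE genes get TSSs within 2 kb of planted increases; the rest keep
    at least 6 kb away so the nearest-gene map separates the two groups."""
    if n_de > n_genes:
        raise ValueError("n_de > n_genes")
    if n_de and len(increases) < n_de:
        raise ValueError("not enough planted increases to anchor DE genes")
    genes: list[GeneModel] = []
    de: dict[str, float] = {}
    levels: dict[str, float] = {}
    span = 5000
    chosen = rng.permutation(len(increases))[:n_de] if n_de else []
    tss_list: list[tuple[int, bool]] = []
    for k in chosen:
        center = increases[k].midpoint
        tss_list.append((center + int(rng.integers(-2000, 2001)), True))
    inc_mids = np.array([iv.midpoint for iv in increases]) if increases else None
    n_bg = n_genes - n_de
    placed = 0
    while placed < n_bg:
        tss = int(rng.integers(1000, genome_length - span - 1000))
        if inc_mids is not None and np.min(np.abs(inc_mids - tss)) < 6000:
            continue
        tss_list.append((tss, False))
        placed += 1
    for gi, (tss, is_de) in enumerate(tss_list):
        gid = f"gene{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            left = min(max(tss, 1000), genome_length - span - 1000)
            exons = [(left, left + 500), (left + 2000, left + 2500),
                     (left + 4200, left + span)]
            utr3 = (left + span - 300, left + span)
            tss = left
        else:
            # biological TSS at the right end of the gene body
            left = min(max(tss - span + 1, 1000), genome_length - span - 1000)
            exons = [(left, left + 800), (left + 2500, left + 3000),
                     (left + 4500, left + span)]
            utr3 = (left, left + 300)
            tss = left + span - 1
        genes.append(GeneModel(gid, chrom, strand, tss, exons, utr3))
        levels[gid] = float(np.exp(rng.normal(np.log(100.0), 0.5)))
        if is_de:
            de[gid] = de_fold
    return genes, de, levels


# ---------------------------------------------------------------------------
# generators


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) with var = mu + dispersion * mu^2; dispersion 0
    degenerates to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion)
    return rng.poisson(lam)


def cut_rate(scenario: SimScenario, condition: str) -> dict[str, np.ndarray]:
    """Per-bp expected cut rate for one condition (before depth scaling)."""
    if condition not in scenario.n_replicates:
        raise ValueError(f"unknown condition {condition!r}")
    rates = {
        c: np.full(n, scenario.lambda_bg)
        for c, n in scenario.chrom_sizes.items()
    }
    for i, d in enumerate(scenario.dhs):
        rates[d.chrom][d.start : d.end] *= scenario.dhs_multiplier[i]
    if condition == INDUCED:
        for i in scenario.planted_increase:
            d = scenario.dhs[i]
            rates[d.chrom][d.start : d.end] *= scenario.fold_change
    if condition in scenario.footprint_conditions:
        half = FOOTPRINT_CORE // 2
        for site in scenario.motif_sites:
            tpl = scenario.templates[site.template]
            c = site.center
            vec = rates[site.interval.chrom]
            vals = tpl.values
            if site.interval.strand == "-":
                vals = vals[::-1]
            lo, hi = c - half, c + half + 1
            vec[lo:hi] *= vals
            vec[max(0, lo - tpl.flank_bp) : lo] *= tpl.flank
            vec[hi : hi + tpl.flank_bp] *= tpl.flank
    return rates


def simulate_cuts(
    scenario: SimScenario, condition: str, replicate: int
) -> CutProfile:
    """Draw one replicate cut profile; deterministic given
    (scenario seed, condition, replicate)."""
    if condition not in scenario.n_replicates:
        raise ValueError(f"unknown condition {condition!r}")
    if not 0 <= replicate < scenario.n_replicates[condition]:
        raise ValueError(f"replicate {replicate} not declared for {condition}")
    rates = cut_rate(scenario, condition)
    depth = scenario.depth_factor.get((condition, replicate), 1.0)
    rng = scenario.rng(10, 0 if condition == UNTREATED else 1, replicate)
    counts = {
        c: _nb_draw(rng, vec * depth, scenario.dispersion).astype(np.int64)
        for c, vec in rates.items()
    }
    return CutProfile(counts, replicate=f"{condition}_{replicate}",
                      condition=condition)


def simulate_all_cuts(scenario: SimScenario) -> dict[str, list[CutProfile]]:
    return {
        cond: [simulate_cuts(scenario, cond, r) for r in range(n)]
        for cond, n in scenario.n_replicates.items()
    }


def simulate_sequence(scenario: SimScenario, pwm: PWM) -> dict[str, str]:
    """Background bases i.i.d. from the PWM's stationary background; at each
    planted site a string sampled per-column from the PWM
    (reverse-complemented for '-' sites)."""
    from .motif import reverse_complement  # local to avoid import cycle

    pi = pwm.background_stationary
    if pi is None:
        pi = np.full(4, 0.25)
    rng = scenario.rng(1)
    bases = np.array(list("ACGT"))
    out = {}
    for chrom, n in scenario.chrom_sizes.items():
        arr = rng.choice(bases, size=n, p=pi)
        for site in scenario.motif_sites:
            if site.interval.chrom != chrom:
                continue
            if pwm.width > len(site.interval):
                raise ValueError("PWM wider than planted site")
            sampled = "".join(
                bases[rng.choice(4, p=pwm.probs[:, j])]
                for j in range(pwm.width)
            )
            if site.interval.strand == "-":
                sampled = reverse_complement(sampled)
            start = site.interval.start
            arr[start : start + pwm.width] = list(sampled)
        out[chrom] = "".join(arr)
    return out


def simulate_expression(scenario: SimScenario):
    """Gene x replicate NB count table plus condition labels.

    Returns (pandas DataFrame indexed by gene id, list of condition labels
    aligned with columns).
    """
    import pandas as pd

    rng = scenario.rng(2)
    cols, conds = [], []
    data = {}
    gene_ids = [g.gene_id for g in scenario.genes]
    base = np.array([scenario.gene_level[g] for g in gene_ids])
    for cond in (UNTREATED, INDUCED):
        fold = np.array(
            [
                scenario.de_genes.get(g, 1.0) if cond == INDUCED else 1.0
                for g in gene_ids
            ]
        )
        for r in range(scenario.n_replicates[cond]):
            name = f"{cond}_{r}"
            mean = base * fold
            data[name] = _nb_draw(rng, mean, scenario.expr_dispersion)
            cols.append(name)
            conds.append(cond)
    df = pd.DataFrame(data, index=gene_ids, columns=cols)
    return df, conds
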