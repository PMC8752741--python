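"""Synthetic inputs with planted ground truth.

The generator emulates the study design: three genotypes (wild type plus
two TF-null mutants), ER stress recovery timepoints 0/12/24 h, tunicamycin
(Tm) vs DMSO mock treatments, three RNA-seq replicates, and two ChIP
replicates per TF × condition × timepoint.  Counts are negative binomial
(variance m + α·m²) with treatment effects applied on the log2 scale, so
planted Δlog2FC values are directly comparable to estimated fold changes.
Genotype-dependent genes have their Tm response attenuated by Δ in the
designated mutant; coexpression-module genes share a latent per-condition
profile; promoters carry UPR cis-elements planted at configurable rates;
Tm-specific ChIP peaks sit on planted ERSE-I instances near target TSSs
while constitutive peaks appear in both conditions with matched strength.

Everything is reproducible: a single seed fans out to per-component seeds
through ``numpy.random.SeedSequence``, so identical configurations give
byte-identical serialized outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cistrome import BUILTIN_CRES, IUPAC, compile_cre, revcomp
from .exceptions import ParameterError
from .io import (PeakSet, write_annotation, write_counts, write_fasta,
                 write_narrowpeak, write_sample_sheet)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ModuleSpec:
    module_id: str
    n_genes: int = 60
    latent_amplitude: float = 2.0
    noise_sd: float = 0.3


@dataclass(frozen=True)
class DdegSpec:
    """Plant genotype-dependent regulation: in ``genotype`` the Tm response of
    a ``fraction`` of all genes is attenuated by ``delta_log2fc``."""

    fraction: float = 0.05
    delta_log2fc: float = 2.0
    genotype: str = "bzip28"


@dataclass(frozen=True)
class PeakSpec:
    n_specific: int = 30
    n_constitutive: int = 20
    peak_width: int = 400
    tm_pfloat_mean: float = 12.0
    tm_pfloat_sd: float = 2.0
    mock_pfloat_mean: float = 10.0
    mock_pfloat_sd: float = 1.5
    jitter_bp: int = 25


def _default_modules():
    return tuple(ModuleSpec(module_id=f"M{i + 1}") for i in range(4))


def _default_ddeg():
    return (DdegSpec(genotype="bzip28"), DdegSpec(genotype="bzip60"))


def _default_peaks():
    return {"bZIP28": PeakSpec(), "bZIP60": PeakSpec()}


def _default_cre_rates():
    return {"ERSE-I": (0.8, 0.05)}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic generator."""

    seed: int = 0
    n_genes: int = 2000
    genotypes: tuple = ("Col0", "bzip28", "bzip60")
    timepoints: tuple = (0, 12, 24)
    n_replicates: int = 3
    nb_dispersion: float = 0.02
    baseline_mean_log: float = 8.0   # log2 of the median baseline count
    baseline_sd_log: float = 1.5
    deg_fraction: float = 0.4
    deg_log2fc: float = 2.0
    module_spec: tuple = field(default_factory=_default_modules)
    ddeg_spec: tuple = field(default_factory=_default_ddeg)
    promoter_length: int = 1000
    gc_content: float = 0.36
    cre_plant_rates: dict = field(default_factory=_default_cre_rates)
    peak_spec: dict = field(default_factory=_default_peaks)
    peak_shared_fraction: float = 0.3   # fraction of specific targets shared between TFs
    n_chromosomes: int = 5
    n_conditions_network: int = 30
    n_background_network: int = 200

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if not 0 <= self.gc_content <= 1:
            raise ParameterError("gc_content must lie in [0, 1]")
        if not 0 <= self.deg_fraction <= 1:
            raise ParameterError("deg_fraction must lie in [0, 1]")
        for spec in self.ddeg_spec:
            if not 0 <= spec.fraction <= 1:
                raise ParameterError("ddeg fractions must lie in [0, 1]")
            if spec.genotype not in self.genotypes:
                raise ParameterError(f"unknown ddeg genotype {spec.genotype!r}")
        for name, (t, b) in self.cre_plant_rates.items():
            if not (0 <= t <= 1 and 0 <= b <= 1):
                raise ParameterError(f"plant rates for {name} must lie in [0, 1]")
        for tf, spec in self.peak_spec.items():
            if spec.peak_width <= 0:
                raise ParameterError(f"peak width for {tf} must be > 0")
        max_span = max(compile_cre(n, c, m).span for n, (c, m) in BUILTIN_CRES.items())
        if self.promoter_length <= max_span:
            raise ParameterError("promoter_length must exceed the longest CRE span")

    def rng(self, component: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(component,))
        )


@dataclass
class GroundTruth:
    """Planted labels for every synthetic input."""

    deg_genes: set = field(default_factory=set)
    deg_sign: dict = field(default_factory=dict)             # gene -> ±1
    ddeg_genes: dict = field(default_factory=dict)           # pair -> set
    module_of_gene: dict = field(default_factory=dict)
    cre_positions: dict = field(default_factory=dict)        # gene -> [(cre, offset, strand)]
    specific_peaks: dict = field(default_factory=dict)       # tf -> set of ids
    constitutive_peaks: dict = field(default_factory=dict)
    peak_target_genes: dict = field(default_factory=dict)    # tf -> set of genes
    hubs: set = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        def enc(x):
            if isinstance(x, set):
                return sorted(x)
            if isinstance(x, dict):
                return {str(k): enc(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [enc(v) for v in x]
            return x
        with open(path, "w") as fh:
            json.dump({k: enc(v) for k, v in asdict(self).items()}, fh,
                      indent=1, sort_keys=True)


def merge_truth(*parts: GroundTruth) -> GroundTruth:
    out = GroundTruth()
    for p in parts:
        out.deg_genes |= p.deg_genes
        out.deg_sign.update(p.deg_sign)
        for k, v in p.ddeg_genes.items():
            out.ddeg_genes.setdefault(k, set()).update(v)
        out.module_of_gene.update(p.module_of_gene)
        out.cre_positions.update(p.cre_positions)
        for d_out, d_in in ((out.specific_peaks, p.specific_peaks),
                            (out.constitutive_peaks, p.constitutive_peaks),
                            (out.peak_target_genes, p.peak_target_genes)):
            for k, v in d_in.items():
                d_out.setdefault(k, set()).update(v)
        out.hubs |= p.hubs
    return out


# ---------------------------------------------------------------------------
# design plan: deterministic gene-role assignment shared by all generators
# ---------------------------------------------------------------------------

@dataclass
class _Plan:
    genes: list
    deg_genes: list
    deg_sign: dict
    ddeg_of_gene: dict      # gene -> DdegSpec
    module_of_gene: dict
    conditions: list        # [(genotype, timepoint), ...]


def _plan(config: SimulationConfig) -> _Plan:
    rng = config.rng(0)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_deg = int(round(config.deg_fraction * config.n_genes))
    perm = list(rng.permutation(genes))
    deg_genes = perm[:n_deg]
    deg_sign = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(deg_genes)}
    cursor = 0
    ddeg_of_gene = {}
    for spec in config.ddeg_spec:
        n = int(round(spec.fraction * config.n_genes))
        chunk = deg_genes[cursor:cursor + n]
        if len(chunk) < n:
            raise ParameterError("not enough DEG genes to plant the requested DDEG fractions")
        for g in chunk:
            ddeg_of_gene[g] = spec
        cursor += n
    module_of_gene = {}
    for mspec in config.module_spec:
        chunk = deg_genes[cursor:cursor + mspec.n_genes]
        if len(chunk) < mspec.n_genes:
            raise ParameterError("not enough DEG genes to plant the requested modules")
        for g in chunk:
            module_of_gene[g] = mspec.module_id
        cursor += mspec.n_genes
    conditions = [(g, t) for g in config.genotypes for t in config.timepoints]
    return _Plan(genes, deg_genes, deg_sign, ddeg_of_gene, module_of_gene, conditions)


def _truth_from_plan(config: SimulationConfig, plan: _Plan) -> GroundTruth:
    truth = GroundTruth(
        deg_genes=set(plan.deg_genes),
        deg_sign=dict(plan.deg_sign),
        module_of_gene=dict(plan.module_of_gene),
    )
    wt = config.genotypes[0]
    per_spec = {}
    for g, spec in plan.ddeg_of_gene.items():
        if spec.delta_log2fc == 0:
            continue  # no planted effect, nothing to recover
        per_spec.setdefault(spec.genotype, set()).add(g)
    for genotype, genes in per_spec.items():
        truth.ddeg_genes[f"{wt}_vs_{genotype}"] = set(genes)
    mutants = [g for g in config.genotypes[1:] if g in per_spec]
    if len(mutants) == 2:
        a, b = mutants
        truth.ddeg_genes[f"{a}_vs_{b}"] = per_spec[a] ^ per_spec[b]
    return truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(config: SimulationConfig):
    """Simulate the genotype × timepoint × treatment count table.

    Returns (counts DataFrame, sample sheet DataFrame, GroundTruth).
    """
    plan = _plan(config)
    truth = _truth_from_plan(config, plan)
    rng = config.rng(1)
    n_genes = config.n_genes
    baseline = 2.0 ** rng.normal(config.baseline_mean_log, config.baseline_sd_log, n_genes)
    gene_index = {g: i for i, g in enumerate(plan.genes)}

    # per-gene per-condition treatment log2FC
    lfc = np.zeros((n_genes, len(plan.conditions)))
    for g in plan.deg_genes:
        lfc[gene_index[g], :] = plan.deg_sign[g] * config.deg_log2fc
    for g, spec in plan.ddeg_of_gene.items():
        for c, (genotype, _) in enumerate(plan.conditions):
            if genotype == spec.genotype:
                lfc[gene_index[g], c] -= plan.deg_sign[g] * spec.delta_log2fc
    for mspec in config.module_spec:
        members = [g for g, m in plan.module_of_gene.items() if m == mspec.module_id]
        latent = rng.normal(0.0, 1.0, len(plan.conditions))
        for g in members:
            noise = rng.normal(0.0, mspec.noise_sd, len(plan.conditions))
            lfc[gene_index[g], :] += mspec.latent_amplitude * latent + noise

    r = 1.0 / config.nb_dispersion
    columns, sheet_rows = {}, []
    for c, (genotype, timepoint) in enumerate(plan.conditions):
        for treatment in ("Tm", "mock"):
            mean = baseline * (2.0 ** lfc[:, c] if treatment == "Tm" else 1.0)
            p = r / (r + mean)
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{genotype}_{timepoint}h_{treatment}_r{rep}"
                columns[sample_id] = rng.negative_binomial(r, p)
                sheet_rows.append((sample_id, genotype, timepoint, treatment, rep))
    counts = pd.DataFrame(columns, index=pd.Index(plan.genes, name="gene_id"))
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "genotype", "timepoint",
                                              "treatment", "replicate"])
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# genome, promoters, planted CREs
# ---------------------------------------------------------------------------

_SLOT = 5000          # bp reserved per gene
_GENE_LEN = 2000


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _BASES[rng.choice(4, size=length, p=probs)]


def _realize(consensus_positions, rng) -> str:
    """Draw one concrete instance of a compiled consensus alternative."""
    letters = []
    for allowed in consensus_positions:
        pool = sorted(allowed) if allowed is not None else list("ACGT")
        letters.append(pool[rng.integers(len(pool))])
    return "".join(letters)


def simulate_genome(config: SimulationConfig):
    """Simulate annotation, promoter sequences and chromosome sequences.

    Promoters are i.i.d. letters at the configured GC content; CREs are
    planted at the configured target/background rates (targets = planted
    genotype-dependent genes).  Promoter sequences are embedded into the
    chromosome sequences so that peak windows cut from the genome contain
    the planted motifs.  Returns (annotation, promoters, genome, truth).
    """
    plan = _plan(config)
    truth = _truth_from_plan(config, plan)
    rng = config.rng(2)
    targets = set().union(*truth.ddeg_genes.values()) if truth.ddeg_genes else set()
    patterns = {name: compile_cre(name, cons, mm) for name, (cons, mm) in BUILTIN_CRES.items()}

    ann_rows = []
    promoters = {}
    chrom_len = ((config.n_genes + config.n_chromosomes - 1) // config.n_chromosomes) * _SLOT + _SLOT
    genome = {f"chr{i + 1}": _random_seq(rng, chrom_len, config.gc_content)
              for i in range(config.n_chromosomes)}

    for i, gene in enumerate(plan.genes):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        slot = (i // config.n_chromosomes) * _SLOT
        strand = "+" if rng.random() < 0.5 else "-"
        prom = _random_seq(rng, config.promoter_length, config.gc_content)
        occupied = []
        planted = []
        for name, (t_rate, b_rate) in sorted(config.cre_plant_rates.items()):
            rate = t_rate if gene in targets else b_rate
            if rng.random() >= rate:
                continue
            pat = patterns[name]
            alt = pat.alternatives[rng.integers(len(pat.alternatives))]
            inst = _realize(alt, rng)
            m_strand = "+" if rng.random() < 0.5 else "-"
            for _ in range(10):
                off = int(rng.integers(0, config.promoter_length - pat.span + 1))
                if all(off + pat.span <= s or off >= e for s, e in occupied):
                    seq = inst if m_strand == "+" else revcomp(inst)
                    prom[off:off + pat.span] = list(seq)
                    occupied.append((off, off + pat.span))
                    planted.append((name, off, m_strand))
                    break
        if planted:
            truth.cre_positions[gene] = planted
        prom_str = "".join(prom)
        promoters[gene] = prom_str
        if strand == "+":
            tss = slot + 500 + config.promoter_length
            start, end = tss, tss + _GENE_LEN
            genome[chrom][tss - config.promoter_length:tss] = list(prom_str)
        else:
            start = slot + 500
            end = start + _GENE_LEN
            tss = end - 1
            genome[chrom][tss + 1:tss + 1 + config.promoter_length] = list(revcomp(prom_str))
        ann_rows.append((gene, chrom, start, end, strand, tss))

    annotation = pd.DataFrame(
        ann_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    genome = {c: "".join(arr) for c, arr in genome.items()}
    return annotation, promoters, genome, truth


def motif_genomic_center(ann_row, offset: int, span: int, promoter_length: int) -> int:
    """Genomic coordinate of a planted promoter motif's center."""
    if ann_row.strand == "+":
        start = ann_row.tss - promoter_length + offset
    else:
        start = ann_row.tss + 1 + promoter_length - offset - span
    return start + span // 2


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------

def simulate_peaks(config: SimulationConfig, annotation: pd.DataFrame,
                   truth: GroundTruth | None = None):
    """Simulate replicated narrowPeak sets per TF × condition × timepoint.

    Tm-specific peaks are placed with their summit on a planted ERSE-I when
    the target gene has one (otherwise near the TSS) and appear only in Tm
    replicates; constitutive peaks appear in Tm and mock with pfloat within
    3-fold.  Replicate intervals are jittered by <= ``jitter_bp``.
    Returns ({tf: [PeakSet, ...]}, truth).
    """
    plan = _plan(config)
    if truth is None:
        truth = _truth_from_plan(config, plan)
    rng = config.rng(3)
    ann = annotation.set_index("gene_id")
    erse_span = compile_cre(*(("ERSE-I",) + BUILTIN_CRES["ERSE-I"])).span
    with_erse = [g for g in plan.genes
                 if any(c == "ERSE-I" for c, _, _ in truth.cre_positions.get(g, []))]
    peaksets: dict[str, list[PeakSet]] = {}
    used_genes: set = set()
    prior_targets: list = []
    for tf, spec in sorted(config.peak_spec.items()):
        # a fraction of specific targets is shared with earlier TFs, mirroring
        # the partially overlapping binding of the two UPR bZIP-TFs
        n_shared = min(int(round(config.peak_shared_fraction * spec.n_specific)),
                       len(prior_targets))
        shared = list(rng.choice(prior_targets, size=n_shared, replace=False)) if n_shared else []
        pool = [g for g in with_erse if g not in used_genes]
        n_fresh = spec.n_specific - len(shared)
        if len(pool) < n_fresh:
            pool = pool + [g for g in plan.genes if g not in used_genes and g not in pool]
        fresh = list(rng.choice(pool, size=n_fresh, replace=False)) if n_fresh else []
        spec_genes = shared + fresh
        used_genes |= set(spec_genes)
        prior_targets = sorted(set(prior_targets) | set(spec_genes))
        const_pool = [g for g in plan.genes if g not in used_genes]
        const_genes = list(rng.choice(const_pool, size=spec.n_constitutive, replace=False)) if spec.n_constitutive else []
        used_genes |= set(const_genes)
        truth.specific_peaks[tf] = {f"{tf}_spec_{g}" for g in spec_genes}
        truth.constitutive_peaks[tf] = {f"{tf}_const_{g}" for g in const_genes}
        truth.peak_target_genes[tf] = set(spec_genes)

        def summit_for(gene):
            row = ann.loc[gene]
            for cre, off, _ in truth.cre_positions.get(gene, []):
                if cre == "ERSE-I":
                    return row.chrom, motif_genomic_center(row, off, erse_span,
                                                          config.promoter_length)
            delta = int(rng.integers(-400, 401))
            return row.chrom, int(row.tss + delta)

        base = {}
        for kind, genes in (("spec", spec_genes), ("const", const_genes)):
            for g in genes:
                chrom, summit = summit_for(g)
                tm_pf = float(max(0.5, rng.normal(spec.tm_pfloat_mean, spec.tm_pfloat_sd)))
                mock_pf = float(tm_pf * rng.uniform(0.5, 1.5))
                base[f"{tf}_{kind}_{g}"] = (chrom, summit, kind, tm_pf, mock_pf)

        sets = []
        for timepoint in config.timepoints:
            for condition in ("Tm", "mock"):
                for rep in (1, 2):
                    rows = []
                    for name, (chrom, summit, kind, tm_pf, mock_pf) in sorted(base.items()):
                        if condition == "mock" and kind == "spec":
                            continue
                        j1 = int(rng.integers(-spec.jitter_bp, spec.jitter_bp + 1))
                        j2 = int(rng.integers(-spec.jitter_bp, spec.jitter_bp + 1))
                        start = summit - spec.peak_width // 2 + j1
                        end = summit + spec.peak_width // 2 + j2
                        start = min(start, summit)
                        end = max(end, summit + 1)
                        pf = tm_pf if condition == "Tm" else mock_pf
                        pf = float(max(0.1, pf + rng.normal(0.0, 0.2)))
                        rows.append((chrom, start, end, name, int(min(1000, pf * 50)),
                                     ".", pf / 2.0, pf, -1.0, summit - start, summit))
                    df = pd.DataFrame(rows, columns=[
                        "chrom", "start", "end", "name", "score", "strand",
                        "signal", "pfloat", "qvalue", "summit_offset", "summit"])
                    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
                    sets.append(PeakSet(df, tf=tf, condition=condition,
                                        timepoint=timepoint, replicate=rep))
        peaksets[tf] = sets
    return peaksets, truth


# ---------------------------------------------------------------------------
# focused scenarios for network and hub recovery
# ---------------------------------------------------------------------------

def simulate_lfc_matrix(config: SimulationConfig, seed: int | None = None):
    """Planted-module log2FC matrix for network recovery.

    Module genes follow their module's latent profile across
    ``n_conditions_network`` conditions (amplitude × latent + noise);
    background genes are unit-variance noise.  Returns (X, truth).
    """
    rng = (config.rng(4) if seed is None
           else np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,))))
    n_cond = config.n_conditions_network
    rows, genes, truth = [], [], GroundTruth()
    for mspec in config.module_spec:
        latent = rng.normal(0.0, 1.0, n_cond)
        for i in range(mspec.n_genes):
            gene = f"{mspec.module_id}_g{i:03d}"
            genes.append(gene)
            truth.module_of_gene[gene] = mspec.module_id
            rows.append(mspec.latent_amplitude * latent + rng.normal(0.0, mspec.noise_sd, n_cond))
    for i in range(config.n_background_network):
        gene = f"bg_g{i:03d}"
        genes.append(gene)
        truth.module_of_gene[gene] = "background"
        rows.append(rng.normal(0.0, 1.0, n_cond))
    X = pd.DataFrame(np.array(rows), index=pd.Index(genes, name="gene_id"),
                     columns=[f"cond{c:02d}" for c in range(n_cond)])
    return X, truth


def simulate_hub_scenario(n_partners: int = 40, hub_corr: float = 0.9,
                          n_background: int = 20, n_conditions: int = 30,
                          seed: int = 0):
    """One hub gene correlated ``hub_corr`` with each of its partners.

    Partners share only the hub-driven component (mutual correlation
    hub_corr²), so the hub has the highest degree.  Returns (X, hub_gene).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    hub = rng.normal(0.0, 1.0, n_conditions)
    rows = {"hub": hub}
    a = hub_corr
    b = np.sqrt(1.0 - a * a)
    for i in range(n_partners):
        rows[f"partner_{i:02d}"] = a * hub + b * rng.normal(0.0, 1.0, n_conditions)
    for i in range(n_background):
        rows[f"bg_{i:02d}"] = rng.normal(0.0, 1.0, n_conditions)
    X = pd.DataFrame(rows).T
    X.index.name = "gene_id"
    X.columns = [f"cond{c:02d}" for c in range(n_conditions)]
    return X, "hub"


def simulate_replicate_lfc(n_genes: int, delta: float, sigma: float,
                           n_reps: int = 3, seed: int = 0):
    """Replicate-level log2FC draws for two genotypes.

    Genotype A responds with mean ``delta``, genotype B with 0; both have
    replicate noise ``sigma``.  Returns (x, y) arrays of shape (n_genes, n_reps).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(6,)))
    x = rng.normal(delta, sigma, (n_genes, n_reps))
    y = rng.normal(0.0, sigma, (n_genes, n_reps))
    return x, y


def simulate_term_map(config: SimulationConfig, truth: GroundTruth,
                      n_random_terms: int = 10, seed: int | None = None) -> dict:
    """Gene → term map with one term per planted module plus random terms."""
    rng = (config.rng(7) if seed is None
           else np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,))))
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    terms = {}
    by_module = {}
    for g, m in truth.module_of_gene.items():
        by_module.setdefault(m, set()).add(g)
    for m, members in sorted(by_module.items()):
        extra = set(rng.choice(genes, size=max(1, len(members) // 10), replace=False))
        terms[f"term_{m}"] = set(members) | extra
    for i in range(n_random_terms):
        size = int(rng.integers(20, 200))
        terms[f"term_rand{i:02d}"] = set(rng.choice(genes, size=size, replace=False))
    return terms


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_inputs(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate every pipeline input and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, sheet, t1 = simulate_counts(config)
    annotation, promoters, genome, t2 = simulate_genome(config)
    peaksets, t3 = simulate_peaks(config, annotation, truth=t2)
    truth = merge_truth(t1, t3)
    write_counts(counts, outdir / "counts.tsv")
    write_sample_sheet(sheet, outdir / "samples.tsv")
    write_annotation(annotation, outdir / "genes.gff3", dialect="gff3")
    write_annotation(annotation, outdir / "genes.bed", dialect="bed")
    write_fasta(promoters, outdir / "promoters.fa")
    write_fasta(genome, outdir / "genome.fa")
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for tf, sets in peaksets.items():
        for ps in sets:
            fn = f"{tf}_{ps.condition}_{ps.timepoint}h_rep{ps.replicate}.narrowPeak"
            write_narrowpeak(ps, peak_dir / fn)
    truth.to_json(outdir / "truth.json")
    return truth
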