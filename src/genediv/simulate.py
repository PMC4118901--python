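"""Synthetic panel, phenotype and Q-matrix generator.

Generates data with the statistical structure the analysis assumes, so
every pipeline stage is testable without external data.  The default
configuration emulates a maize candidate-gene resequencing panel: an
80-line alignment over a 7-region gene model (520 bp promoter, three
exons of 624/162/534 bp, two introns of 131/128 bp, 337 bp 3'-UTR) with

* 22 planted SNPs distributed 7/5/0/0/0/4/6 across the regions, exactly
  one of them a singleton (in the promoter);
* 8 indel events spanning 37 columns (region pattern 1/3/19/0/7/6/1),
  two of them singletons, including a tri-allelic in-frame coding
  deletion (no-deletion / -3 / -6 over the same six exon columns,
  removing one E or an ED pair from the protein);
* 11 full-length haplotypes with exact counts 29/16/18/9/2/1/1/1/1/1/1
  that collapse to 6 CDS haplotypes of 32/18/16/9/3/2 lines;
* one recombinant background (a single crossover in intron 1 between two
  haplotype backgrounds), so the four-gamete test finds exactly one
  recombination interval — switch it off for tree-compatible (Rm = 0)
  panels;
* 3-subpopulation admixture tilted by haplotype, and 11 quantitative
  traits, one of which carries the coding deletion as a causal variant
  explaining a configurable fraction (default 9.26%) of its variance.

Haplotype assignment uses exact counts by default so haplotype-diversity
values are reproducible deterministically; multinomial sampling is
available by flag.  All randomness flows from one integer seed;
identical seeds give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import (
    GAP,
    AlignedPanel,
    GeneModel,
    PhenotypeTable,
    QMatrix,
    Region,
    logger,
    write_alignment,
    write_gene_model,
    write_phenotypes,
    write_qmatrix,
)

import pandas as pd

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantedSNP:
    position: int              # 1-based alignment column
    carriers: tuple[int, ...]  # haplotype indices (0-based) carrying the alternate


@dataclass
class DeletionAllele:
    carriers: tuple[int, ...]
    offset: int  # first gapped column within the event block
    length: int  # number of gapped columns


@dataclass
class PlantedIndel:
    start: int  # 1-based first column of the event block
    span: int
    alleles: list[DeletionAllele]


@dataclass
class TraitSpec:
    mean: float
    sd: float
    anova_f: float = 60.0          # drives within-line replicate noise
    pop_shifts: tuple[float, ...] = ()  # additive subpopulation shifts, units of sd
    causal_target_r2: float = 0.0  # fraction of variance the causal variant explains
    causal_sign: int = -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.causal_target_r2 <= 0.9:
            raise ValueError("target R^2 must lie in [0, 0.9]")


@dataclass
class SimConfig:
    n_samples: int = 80
    hap_counts: tuple[int, ...] = (29, 16, 18, 9, 1, 1, 2, 1, 1, 1, 1)
    model: GeneModel = field(default_factory=lambda: zmbt1_gene_model())
    snps: list[PlantedSNP] = field(default_factory=list)
    indels: list[PlantedIndel] = field(default_factory=list)
    causal_indel_start: int | None = None  # block start of the causal deletion event
    home_pop: tuple[int, ...] = ()
    k_subpops: int = 3
    dirichlet_base: float = 0.5
    dirichlet_boost: float = 6.0
    traits: dict[str, TraitSpec] = field(default_factory=dict)
    replicates: int = 2
    multinomial: bool = False
    recombination: bool = True
    crossover: int = 1160  # recombinant switches background after this column

    def __post_init__(self) -> None:
        if sum(self.hap_counts) != self.n_samples:
            raise ValueError("haplotype counts must sum to n_samples")


def zmbt1_gene_model() -> GeneModel:
    """The default 7-region gene model (total 2,436 columns, CDS 1,320)."""
    return GeneModel(
        regions=[
            Region("promoter", "promoter", 1, 520),
            Region("exon1", "exon", 521, 1144),
            Region("intron1", "intron", 1145, 1275),
            Region("exon2", "exon", 1276, 1437),
            Region("intron2", "intron", 1438, 1565),
            Region("exon3", "exon", 1566, 2099),
            Region("utr3", "utr3", 2100, 2436),
        ],
        cds_region_names=["exon1", "exon2", "exon3"],
        strand="+",
    )


# haplotype indices: 0..10 <-> the 11 full-length haplotypes; CDS classes:
#   {0,4,7,9} -> CDS 1 (reference-like), {1} -> 2, {2} -> 3, {3} -> 4,
#   {5,8} -> 5, {6,10} -> 6.  Haplotypes 5 and 8 share a recombinant
#   background (haplotype 3's alleles left of the crossover in intron 1,
#   a private exon3/3'-UTR background to the right) and differ from each
#   other only by an intron indel.
CDS_CLASS_OF_HAP = (0, 1, 2, 3, 0, 4, 5, 0, 4, 0, 5)


def default_config(recombination: bool = True) -> SimConfig:
    """The study-condition configuration described in the module docstring."""
    H2, H3, H4, H6, H7, H9, H11 = 1, 2, 3, 5, 6, 8, 10  # 0-based hap indices
    H5, H8, H10 = 4, 7, 9
    # with the crossover on, the two CDS-class-5 lines carry haplotype 4's
    # alleles left of the intron-1 junction (including the nonsynonymous
    # exon1 SNP), which leaves exactly one reduced four-gamete interval
    rec = (H6, H9) if recombination else ()

    snps = [
        # promoter: 7 SNPs, one singleton (position 320)
        PlantedSNP(40, (H2,)),
        PlantedSNP(120, (H2, H3)),
        PlantedSNP(200, (H2, H3)),
        PlantedSNP(260, (H4,) + rec),
        PlantedSNP(320, (H5,)),              # the singleton SNP
        PlantedSNP(380, (H7, H11)),
        PlantedSNP(450, (H2,)),
        # exon1: 5 SNPs (third-position sites; 820 is the nonsynonymous one)
        PlantedSNP(559, (H2,)),
        PlantedSNP(700, (H2, H3)),
        PlantedSNP(820, (H4,) + rec),        # ATA -> ATG, I -> M
        PlantedSNP(940, (H7, H11)),
        PlantedSNP(1060, (H2,)),
        # exon3: 4 SNPs (synonymous third positions)
        PlantedSNP(1601, (H2, H3)),
        PlantedSNP(1700, (H6, H9)),
        PlantedSNP(1850, (H7, H11)),
        PlantedSNP(1949, (H2,)),
        # 3'-UTR: 6 SNPs (2200 partially overlaps the recombinant flank,
        # yielding the single four-gamete interval when the crossover is on)
        PlantedSNP(2150, (H2,)),
        PlantedSNP(2200, (H4, H5, H8, H10)),
        PlantedSNP(2250, (H2, H3)),
        PlantedSNP(2300, (H4, H5, H8, H10)),
        PlantedSNP(2350, (H7, H11)),
        PlantedSNP(2400, (H6, H9)),
    ]

    indels = [
        PlantedIndel(480, 1, [DeletionAllele((H8,), 0, 1)]),            # promoter, singleton
        PlantedIndel(998, 3, [DeletionAllele((H2,), 0, 3)]),            # exon1, in-frame 1-residue del
        PlantedIndel(1150, 6, [DeletionAllele((H2,), 0, 6)]),           # intron1
        PlantedIndel(1180, 6, [DeletionAllele((H2, H3), 0, 6)]),        # intron1
        PlantedIndel(1210, 7, [DeletionAllele((H2, H7), 0, 7)]),        # intron1
        PlantedIndel(1480, 7, [DeletionAllele((H2, H3, H6), 0, 7)]),    # intron2; also the
        # sole difference between the two CDS-class-5 lines
        PlantedIndel(1788, 6, [DeletionAllele((H3, H4), 0, 3),          # exon3: -3 (E)
                               DeletionAllele((H7, H11), 0, 6)]),       # and -6 (ED)
        PlantedIndel(2420, 1, [DeletionAllele((H10,), 0, 1)]),          # 3'-UTR, singleton
    ]

    traits = {
        # pasting traits (viscosity/time/temperature units)
        "PV": TraitSpec(1317.013, 405.135, 130.35, pop_shifts=(-0.8, 0.0, 0.8)),
        "TV": TraitSpec(926.856, 250.758, 77.74),
        "BD": TraitSpec(390.156, 216.227, 99.17),
        "FV": TraitSpec(2575.488, 841.476, 258.13),
        "SB": TraitSpec(1258.563, 593.455, 235.29),
        "PT": TraitSpec(5.336, 0.391, 46.07),
        "PTP": TraitSpec(72.759, 2.641, 69.43),
        # gelatinization traits; dH carries the causal coding deletion
        "To": TraitSpec(70.912, 1.219, 12.82),
        "Tp": TraitSpec(75.591, 1.037, 11.28),
        "Tc": TraitSpec(81.266, 1.989, 62.73),
        "dH": TraitSpec(6.225, 1.008, 5.62, causal_target_r2=0.0926, causal_sign=-1),
    }

    # home subpopulations cut across the causal carriers (haplotypes 2 and
    # 3 sit in different groups) so the deletion is not a proxy for Q
    return SimConfig(
        snps=snps,
        indels=indels,
        causal_indel_start=1788,
        home_pop=(0, 1, 0, 1, 0, 2, 2, 1, 2, 2, 2),
        traits=traits,
        recombination=recombination,
    )


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _random_reference(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Reference sequence: random bases, stop-free random codons over the
    CDS, fixed codons where planted variants need a defined context."""
    L = cfg.model.length
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=L)
    sense_codons = sorted({a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS)
    cds_cols = cfg.model.cds_columns  # 1-based, codon-aligned per region lengths
    for k in range(0, len(cds_cols), 3):
        codon = sense_codons[rng.integers(len(sense_codons))]
        for off in range(3):
            ref[cds_cols[k + off] - 1] = codon[off]
    # anchored contexts
    ref[520:523] = list("ATG")    # start codon
    ref[2096:2099] = list("TAA")  # terminal stop
    coding_positions = set(int(c) for c in cds_cols)
    for snp in cfg.snps:
        if snp.position in coding_positions and snp.position != 820:
            # third position of a 4-fold degenerate alanine codon -> synonymous
            ref[snp.position - 3] = "G"
            ref[snp.position - 2] = "C"
    ref[817:820] = list("ATA")    # isoleucine; A->G third-position change is I->M
    if cfg.causal_indel_start:
        s = cfg.causal_indel_start - 1
        ref[s:s + 3] = list("GAG")      # E
        ref[s + 3:s + 6] = list("GAT")  # D
    return ref


def _haplotype_sequences(cfg: SimConfig, ref: np.ndarray) -> np.ndarray:
    n_haps = len(cfg.hap_counts)
    seqs = np.tile(ref, (n_haps, 1)).astype("U1")
    for snp in cfg.snps:
        alt = _TRANSITION[str(ref[snp.position - 1])]
        for h in snp.carriers:
            seqs[h, snp.position - 1] = alt
    for ev in cfg.indels:
        for allele in ev.alleles:
            lo = ev.start - 1 + allele.offset
            for h in allele.carriers:
                seqs[h, lo:lo + allele.length] = GAP
    return seqs


def simulate_panel(cfg: SimConfig | None = None, seed: int = 0) -> tuple[AlignedPanel, dict]:
    """Build the aligned panel and the planted-truth record.

    Returns ``(panel, truth)``; the truth dict lists every planted SNP and
    indel with its carrier samples, the haplotype assignment, the causal
    variant and (when the crossover is on) the recombination interval
    bracketing it — everything needed to verify downstream modules.
    """
    cfg = cfg or default_config()
    rng = np.random.default_rng(seed)
    ref = _random_reference(cfg, rng)
    hap_seqs = _haplotype_sequences(cfg, ref)

    n_haps = len(cfg.hap_counts)
    if cfg.multinomial:
        assignment = rng.choice(n_haps, size=cfg.n_samples,
                                p=np.asarray(cfg.hap_counts) / cfg.n_samples)
    else:
        assignment = np.repeat(np.arange(n_haps), cfg.hap_counts)
        assignment = rng.permutation(assignment)
    sample_ids = [f"IL{i + 1:03d}" for i in range(cfg.n_samples)]
    panel = AlignedPanel(sample_ids, hap_seqs[assignment], "B73", ref.copy())

    hap_of = {s: int(h) for s, h in zip(sample_ids, assignment)}
    carriers_of_hapset = lambda haps: sorted(s for s, h in hap_of.items() if h in haps)  # noqa: E731
    truth: dict = {
        "seed": int(seed),
        "n_samples": cfg.n_samples,
        "recombination": cfg.recombination,
        "haplotype_of_sample": hap_of,
        "cds_class_of_hap": list(CDS_CLASS_OF_HAP[:n_haps]),
        "hap_counts": list(cfg.hap_counts),
        "snps": [
            {"position": s.position, "ref": str(ref[s.position - 1]),
             "alt": _TRANSITION[str(ref[s.position - 1])],
             "carriers": carriers_of_hapset(s.carriers)}
            for s in cfg.snps
        ],
        "indels": [
            {"start": ev.start, "span": ev.span,
             "alleles": [{"offset": a.offset, "length": a.length,
                          "carriers": carriers_of_hapset(a.carriers)}
                         for a in ev.alleles]}
            for ev in cfg.indels
        ],
        "n_indel_sites": sum(ev.span for ev in cfg.indels),
    }
    if cfg.causal_indel_start is not None:
        causal = next(ev for ev in cfg.indels if ev.start == cfg.causal_indel_start)
        truth["causal"] = {
            "kind": "indel", "start": causal.start,
            "carriers": sorted(set(s for a in causal.alleles for s in carriers_of_hapset(a.carriers))),
            "primary_allele_carriers": carriers_of_hapset(causal.alleles[0].carriers),
        }
    if cfg.recombination:
        # incompatibility bracket implied by the crossover design: the
        # nonsynonymous exon1 SNP the recombinant shares with its left
        # donor and the leftmost right-side SNP private to the donor clade
        truth["expected_rm_interval"] = [820, 2200]
    logger.info("simulated panel: %d samples x %d columns, %d SNPs, %d indel events",
                panel.n_samples, panel.length, len(cfg.snps), len(cfg.indels))
    return panel, truth


# ---------------------------------------------------------------------------
# Q matrix and phenotypes
# ---------------------------------------------------------------------------

def simulate_q(cfg: SimConfig, truth: dict, seed: int = 0) -> QMatrix:
    """Dirichlet admixture proportions tilted toward each line's home
    subpopulation (determined by its haplotype)."""
    rng = np.random.default_rng(seed + 1)
    samples = list(truth["haplotype_of_sample"])
    if cfg.k_subpops == 1:
        return QMatrix(samples, np.ones((len(samples), 1)))
    rows = np.empty((len(samples), cfg.k_subpops))
    for i, s in enumerate(samples):
        home = cfg.home_pop[truth["haplotype_of_sample"][s]]
        alpha = np.full(cfg.k_subpops, cfg.dirichlet_base)
        alpha[home] += cfg.dirichlet_boost
        rows[i] = rng.dirichlet(alpha)
    return QMatrix(samples, rows)


def causal_effect_size(target_r2: float, sd: float, v_x: float) -> float:
    """Allele effect beta reaching the target variance fraction given the
    effective contrast variance v_x:
    beta = sd * sqrt(R2 / ((1 - R2) * v_x))."""
    if target_r2 <= 0:
        return 0.0
    return sd * float(np.sqrt(target_r2 / ((1.0 - target_r2) * v_x)))


def simulate_phenotypes(
    cfg: SimConfig, truth: dict, q: QMatrix | None = None, seed: int = 0
) -> PhenotypeTable:
    """Trait values: mean + beta * carrier + Q-weighted subpopulation
    shifts + N(0, sd^2), replicated with within-line noise calibrated so
    the across-line ANOVA F lands near each trait's ``anova_f``.

    The causal effect beta is solved from the target marker R^2 given the
    realized carrier frequency of the causal event's primary allele.
    """
    rng = np.random.default_rng(seed + 2)
    samples = list(truth["haplotype_of_sample"])
    n = len(samples)
    causal = truth.get("causal")
    carrier = np.zeros(n)
    if causal is not None:
        carrier = np.array([1.0 if s in set(causal["carriers"]) else 0.0 for s in samples])
        primary = np.array([s in set(causal["primary_allele_carriers"]) for s in samples])
        # the GLM contrasts the primary deletion allele against no-deletion
        # within the samples carrying neither rarer allele, with Q as
        # covariates: the planted R^2 is therefore calibrated against the
        # Q-residualized contrast variance on that subset
        in_contrast = primary | (carrier == 0)
        x_sub = primary[in_contrast].astype(float)
        if q is not None and q.design_columns().size:
            Xq = np.column_stack([np.ones(int(in_contrast.sum())),
                                  q.design_columns()[in_contrast]])
            resid = x_sub - Xq @ np.linalg.lstsq(Xq, x_sub, rcond=None)[0]
            v_x = float(np.mean(resid**2))
        else:
            v_x = float(np.var(x_sub))
    records: dict[str, np.ndarray] = {}
    betas: dict[str, float] = {}
    for name, spec in cfg.traits.items():
        line_val = np.full(n, spec.mean)
        if spec.pop_shifts and q is not None:
            shifts = np.asarray(spec.pop_shifts) * spec.sd
            line_val = line_val + q.values @ shifts
        beta = 0.0
        if causal is not None and spec.causal_target_r2 > 0:
            rep_sd = (spec.sd * np.sqrt(cfg.replicates / (spec.anova_f - 1.0))
                      if cfg.replicates > 1 and spec.anova_f > 1 else 0.0)
            # calibrate at the line-mean level, where association runs:
            # replicate noise survives averaging as rep_sd^2 / replicates
            sd_eff = float(np.sqrt(spec.sd**2 + rep_sd**2 / max(cfg.replicates, 1)))
            beta = spec.causal_sign * causal_effect_size(spec.causal_target_r2, sd_eff, v_x)
            line_val = line_val + beta * carrier
        betas[name] = beta
        line_val = line_val + rng.normal(0.0, spec.sd, size=n)
        records[name] = line_val

    rows = []
    for r in range(cfg.replicates):
        for i, s in enumerate(samples):
            rec = {"line": s, "replicate": r + 1}
            for name, spec in cfg.traits.items():
                rep_sd = (spec.sd * np.sqrt(cfg.replicates / (spec.anova_f - 1.0))
                          if cfg.replicates > 1 and spec.anova_f > 1 else 0.0)
                rec[name] = records[name][i] + rng.normal(0.0, rep_sd)
            rows.append(rec)
    truth["trait_betas"] = betas
    return PhenotypeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# neutral-equilibrium mode
# ---------------------------------------------------------------------------

def simulate_neutral_panel(n: int, S: int, L: int, seed: int = 0) -> AlignedPanel:
    """Neutral-equilibrium panel: a Kingman-coalescent genealogy (pairwise
    exponential coalescence) with exactly ``S`` infinite-sites mutations
    placed on branches proportionally to length, at distinct random
    columns.  Intended for sanity bands on the neutrality tests, not as a
    full population simulator (no recombination, no gene conversion)."""
    rng = np.random.default_rng(seed)
    active = [frozenset([i]) for i in range(n)]
    birth = {fs: 0.0 for fs in active}
    branches: list[tuple[frozenset, float]] = []
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[j], active[i]
        for child in (a, b):
            branches.append((child, t - birth[child]))
        merged = active[i] | active[j]
        del active[j], active[i]
        active.append(merged)
        birth[merged] = t
    lens = np.array([bl for _, bl in branches])
    cols = np.sort(rng.choice(L, size=min(S, L), replace=False))
    ref = rng.choice(np.array(list("ACGT")), size=L)
    rows = np.tile(ref, (n, 1)).astype("U1")
    picks = rng.choice(len(branches), size=len(cols), p=lens / lens.sum())
    for col, b in zip(cols, picks):
        leafset = branches[b][0]
        alt = _TRANSITION[str(ref[col])]
        for leaf in leafset:
            rows[leaf, col] = alt
    return AlignedPanel([f"N{i + 1:03d}" for i in range(n)], rows)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig | None = None, seed: int = 0, out_dir: str | Path = ".") -> dict:
    """Run the full generator and write alignment.fasta, gene_model.yaml,
    phenotypes.csv, qmatrix.tsv and truth.json under ``out_dir``."""
    cfg = cfg or default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel(cfg, seed)
    q = simulate_q(cfg, truth, seed)
    phen = simulate_phenotypes(cfg, truth, q, seed)
    write_alignment(panel, out / "alignment.fasta")
    write_gene_model(cfg.model, out / "gene_model.yaml")
    write_phenotypes(phen, out / "phenotypes.csv")
    write_qmatrix(q, out / "qmatrix.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    # run config consumed by the downstream CLI stages
    import yaml

    with open(out / "genediv.yaml", "w") as fh:
        yaml.safe_dump({
            # bare filenames: resolved against the run directory by the CLI
            "alignment": "alignment.fasta",
            "gene_model": "gene_model.yaml",
            "phenotypes": "phenotypes.csv",
            "qmatrix": "qmatrix.tsv",
            "reference_id": panel.reference_id,
            "gene_name": "ZmBT1",
        }, fh, sort_keys=False)
    return truth
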