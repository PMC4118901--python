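"""Variant discovery on a gapped alignment.

Derives the variant table from an :class:`~genediv.io_core.AlignedPanel`:
SNPs from polymorphic gap-free columns, indel events from maximal runs of
gap-containing columns, site classification (singleton vs parsimony
informative) and coding-consequence annotation against the majority-allele
CDS.

Conventions (chosen to match locus-survey bookkeeping):

* an *indel event* is one maximal contiguous block of gap-containing
  columns, possibly multi-allelic (e.g. no deletion / -3 / -6 over the
  same six columns);
* "number of indels" counts events, "number of indel sites" counts the
  alignment columns those events span;
* ``N`` bases are missing data — they never create a variant and are
  excluded from allele counts;
* ties for the major allele break toward the reference allele when a
  reference row is present, else lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_core import GAP, MISSING_BASE, AlignedPanel, GeneModel, logger

MISSING = "."

CODING_EFFECTS = (
    "noncoding", "synonymous", "nonsynonymous",
    "inframe_del", "inframe_ins", "frameshift", "NA",
)


@dataclass
class Variant:
    """One SNP or indel event.

    ``alleles`` are observed allele strings ordered major-first; for indel
    events an allele is the sample's literal text over the event block
    (gaps included).  ``genotypes`` holds one allele string per sample,
    ``"."`` for missing (any ``N`` in the window).
    """

    id: str
    kind: str  # "snp" | "indel"
    position: int  # first affected column, 1-based
    span: int
    alleles: list[str]
    genotypes: np.ndarray
    region: str | None = None
    site_class: str | None = None  # "singleton" | "parsimony_informative"
    coding_effect: str = "NA"

    @property
    def counts(self) -> dict[str, int]:
        g = self.genotypes
        return {a: int(np.sum(g == a)) for a in self.alleles}

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.genotypes == MISSING))

    @property
    def allele_lengths(self) -> dict[str, int]:
        """Non-gap length of each allele (deletion sizes fall out as
        differences from the longest allele)."""
        return {a: len(a.replace(GAP, "")) for a in self.alleles}

    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2


@dataclass
class VariantTable:
    """The bridge from alignment to statistics and association."""

    sample_ids: list[str]
    variants: list[Variant] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def snps(self) -> list[Variant]:
        return [v for v in self.variants if v.kind == "snp"]

    def indels(self) -> list[Variant]:
        return [v for v in self.variants if v.kind == "indel"]

    def __len__(self) -> int:
        return len(self.variants)

    def get(self, variant_id: str) -> Variant:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise KeyError(variant_id)

    def sorted(self) -> "VariantTable":
        return VariantTable(self.sample_ids, sorted(self.variants, key=lambda v: v.position))

    # -- serialisation ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for v in self.variants:
            rec = {
                "id": v.id,
                "kind": v.kind,
                "position": v.position,
                "span": v.span,
                "alleles": ",".join(v.alleles),
                "region": v.region if v.region is not None else "NA",
                "class": v.site_class if v.site_class is not None else "NA",
                "coding_effect": v.coding_effect,
            }
            for sid, g in zip(self.sample_ids, v.genotypes):
                rec[sid] = g
            recs.append(rec)
        return pd.DataFrame(recs)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "VariantTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        meta = ["id", "kind", "position", "span", "alleles", "region", "class", "coding_effect"]
        sample_ids = [c for c in df.columns if c not in meta]
        variants = []
        for _, row in df.iterrows():
            variants.append(Variant(
                id=row["id"],
                kind=row["kind"],
                position=int(row["position"]),
                span=int(row["span"]),
                alleles=row["alleles"].split(","),
                genotypes=np.array([row[s] for s in sample_ids], dtype=object),
                region=None if row["region"] == "NA" else row["region"],
                site_class=None if row["class"] == "NA" else row["class"],
                coding_effect=row["coding_effect"],
            ))
        return cls(sample_ids, variants)

    def to_vcf(self, path: str | Path, chrom: str = "gene") -> None:
        """Minimal VCF-style export: POS is the alignment column, indel
        alleles are symbolic ``<DEL>`` with ``SPAN`` in INFO."""
        lines = ["##fileformat=VCFv4.2",
                 '##INFO=<ID=SPAN,Number=1,Type=Integer,Description="Affected alignment columns">',
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        for v in self.sorted().variants:
            if v.kind == "snp":
                ref, alts = v.alleles[0], ",".join(v.alleles[1:])
            else:
                ref, alts = v.alleles[0].replace(GAP, "") or "<REF>", ",".join(
                    "<DEL>" if len(a.replace(GAP, "")) < len(v.alleles[0].replace(GAP, "")) else "<INS>"
                    for a in v.alleles[1:])
            lines.append(f"{chrom}\t{v.position}\t{v.id}\t{ref}\t{alts}\t.\t.\tSPAN={v.span}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def gap_columns(panel: AlignedPanel) -> np.ndarray:
    """Boolean mask over columns containing a gap in any sample (these
    belong to indel events and are excluded from SNP calling)."""
    return (panel.rows == GAP).any(axis=0)


def _order_alleles(alleles: dict[str, int], ref_allele: str | None) -> list[str]:
    """Descending count; ties toward the reference allele, else lexicographic."""
    def key(a: str):
        return (-alleles[a], 0 if a == ref_allele else 1, a)
    return sorted(alleles, key=key)


def call_snps(panel: AlignedPanel, model: GeneModel | None = None) -> VariantTable:
    """One SNP per polymorphic gap-free column; N bases are missing."""
    is_gap = gap_columns(panel)
    variants = []
    for col in range(panel.length):
        if is_gap[col]:
            continue
        bases = panel.rows[:, col]
        called = bases[bases != MISSING_BASE]
        uniq, counts = np.unique(called, return_counts=True)
        if len(uniq) < 2:
            continue
        ref = str(panel.reference_seq[col]) if panel.reference_seq is not None else None
        alleles = _order_alleles(dict(zip(uniq.tolist(), counts.tolist())), ref)
        genotypes = np.where(bases == MISSING_BASE, MISSING, bases).astype(object)
        variants.append(Variant(
            id="", kind="snp", position=col + 1, span=1,
            alleles=alleles, genotypes=genotypes,
            region=model.region_of(col + 1) if model is not None else None,
        ))
    for i, v in enumerate(variants, 1):
        v.id = f"snp{i}"
    logger.info("called %d SNPs on %d gap-free columns", len(variants), int((~is_gap).sum()))
    return VariantTable(list(panel.sample_ids), variants)


def call_indels(panel: AlignedPanel, model: GeneModel | None = None) -> VariantTable:
    """Maximal runs of gap-containing columns become one (possibly
    multi-allelic) indel event each."""
    is_gap = gap_columns(panel)
    variants = []
    col = 0
    while col < panel.length:
        if not is_gap[col]:
            col += 1
            continue
        start = col
        while col < panel.length and is_gap[col]:
            col += 1
        block = panel.rows[:, start:col]
        texts = np.array(["".join(row) for row in block], dtype=object)
        missing = np.array([MISSING_BASE in t for t in texts])
        genotypes = np.where(missing, MISSING, texts).astype(object)
        called = genotypes[genotypes != MISSING]
        uniq, counts = np.unique(called.astype(str), return_counts=True)
        ref = ("".join(panel.reference_seq[start:col])
               if panel.reference_seq is not None else None)
        alleles = _order_alleles(dict(zip(uniq.tolist(), counts.tolist())), ref)
        variants.append(Variant(
            id="", kind="indel", position=start + 1, span=col - start,
            alleles=alleles, genotypes=genotypes,
            region=model.region_of(start + 1) if model is not None else None,
        ))
    for i, v in enumerate(variants, 1):
        v.id = f"indel{i}"
    logger.info("called %d indel events over %d gap columns", len(variants), int(is_gap.sum()))
    return VariantTable(list(panel.sample_ids), variants)


def call_variants(panel: AlignedPanel, model: GeneModel | None = None) -> VariantTable:
    """Full scan: SNPs + indels, classified and (if a model with a CDS is
    given) annotated for coding consequences, sorted by position."""
    vt = VariantTable(
        list(panel.sample_ids),
        call_snps(panel, model).variants + call_indels(panel, model).variants,
    ).sorted()
    vt = classify_sites(vt, panel.n_samples)
    if model is not None and model.cds_region_names:
        vt = annotate_coding_effect(vt, panel, model)
    return vt


def classify_sites(vt: VariantTable, n: int | None = None) -> VariantTable:
    """Label every variant singleton (exactly one sample carries a
    non-major allele) or parsimony_informative."""
    for v in vt.variants:
        counts = v.counts
        minor_carriers = sum(c for a, c in counts.items() if a != v.alleles[0])
        v.site_class = "singleton" if minor_carriers == 1 else "parsimony_informative"
    return vt


# ---------------------------------------------------------------------------
# coding consequences
# ---------------------------------------------------------------------------

def _consensus_cds(panel: AlignedPanel, model: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Majority-allele base per CDS column (gap column majority may be a
    gap).  Returns (bases, cds_columns)."""
    cols = model.cds_columns
    bases = []
    for pos in cols:
        col = panel.rows[:, pos - 1]
        called = col[col != MISSING_BASE]
        uniq, counts = np.unique(called, return_counts=True)
        ref = str(panel.reference_seq[pos - 1]) if panel.reference_seq is not None else None
        bases.append(_order_alleles(dict(zip(uniq.tolist(), counts.tolist())), ref)[0])
    return np.array(bases, dtype="U1"), cols


def translate_cds(seq: str, strand: str = "+") -> str:
    """Translate an ungapped CDS string with the standard genetic code."""
    s = Seq(seq.replace(GAP, ""))
    if strand == "-":
        s = s.reverse_complement()
    return str(s.translate())


def annotate_coding_effect(vt: VariantTable, panel: AlignedPanel, model: GeneModel) -> VariantTable:
    """Annotate each variant's consequence on the protein.

    SNPs inside the CDS are labelled synonymous/nonsynonymous by swapping
    the minor allele into the majority-allele codon; coding indel events
    are in-frame when every allele-length difference is a multiple of 3,
    frameshift otherwise.  An internal stop introduced by an alternate
    allele is flagged with a warning, not an error.
    """
    consensus, cds_cols = _consensus_cds(panel, model)
    col_to_cds = {int(pos): i for i, pos in enumerate(cds_cols)}
    for v in vt.variants:
        if v.position not in col_to_cds and not any(
            (v.position + off) in col_to_cds for off in range(v.span)
        ):
            v.coding_effect = "noncoding"
            continue
        if v.kind == "snp":
            ungapped = consensus != GAP
            # index of this SNP among ungapped CDS bases
            cds_idx = col_to_cds[v.position]
            aa_idx = int(np.sum(ungapped[:cds_idx]))  # offset after dropping gap columns
            codon_i = aa_idx // 3
            base_seq = "".join(consensus[ungapped])
            effect = "synonymous"
            for alt in v.alleles[1:]:
                mutated = list(base_seq)
                mutated[aa_idx] = alt
                ref_aa = translate_cds(base_seq, model.strand)
                alt_aa = translate_cds("".join(mutated), model.strand)
                if ref_aa != alt_aa:
                    effect = "nonsynonymous"
                if "*" in alt_aa[:-1]:
                    logger.warning("%s introduces an internal stop codon (codon %d)", v.id, codon_i + 1)
            v.coding_effect = effect
        else:
            lengths = sorted(set(v.allele_lengths.values()), reverse=True)
            diffs = [lengths[0] - l for l in lengths[1:]]
            if all(d % 3 == 0 for d in diffs):
                major_len = v.allele_lengths[v.alleles[0]]
                v.coding_effect = ("inframe_del"
                                   if any(v.allele_lengths[a] < major_len for a in v.alleles[1:])
                                   else "inframe_ins")
            else:
                v.coding_effect = "frameshift"
    return vt


# ---------------------------------------------------------------------------
# per-region bookkeeping
# ---------------------------------------------------------------------------

def summarize_variant_regions(vt: VariantTable, model: GeneModel) -> pd.DataFrame:
    """Per-region variant bookkeeping: events vs sites vs mean indel length.

    Indel events are attributed to the region containing their first
    column.  ``mean_indel_length = n_indel_sites / n_indel_events`` (NaN
    with zero events).  The "entire" row aggregates all regions.
    """
    rows = []
    regions = list(model.regions) + [None]
    for region in regions:
        if region is None:
            name, length = "entire", sum(r.length for r in model.regions)
            in_region = lambda v: True  # noqa: E731
        else:
            name, length = region.name, region.length
            in_region = lambda v, r=region: r.start <= v.position <= r.end  # noqa: E731
        snps = [v for v in vt.snps() if in_region(v)]
        indels = [v for v in vt.indels() if in_region(v)]
        n_sites = sum(v.span for v in indels)
        rows.append({
            "region": name,
            "length": length,
            "n_variants": len(snps) + len(indels),
            "n_snps": len(snps),
            "n_indel_events": len(indels),
            "n_indel_sites": n_sites,
            "mean_indel_length": (n_sites / len(indels)) if indels else np.nan,
        })
    return pd.DataFrame(rows)
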