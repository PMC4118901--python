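"""Haplotype collapsing, haplotype diversity, protein haplotypes.

Identical aligned sequences (gaps significant) are grouped into
haplotypes over either the full amplicon or the CDS columns; haplotype
diversity is the standard unbiased heterozygosity
Hd = (n/(n-1)) * (1 - sum p_i^2).  CDS haplotypes are translated to
proteins, differences (substitutions, in-frame residue deletions) are
reported against the longest protein allele, and protein variants are
intersected with configured domain intervals (e.g. mitochondrial-carrier
domain spans on the reference protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import GAP, MISSING_BASE, AlignedPanel, GeneModel, logger
from .variant_scan import translate_cds


@dataclass
class Haplotype:
    id: str
    sequence: str  # representative aligned sequence over the column set
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    scope: str  # "full_length" | "cds"
    haplotypes: list[Haplotype]
    n: int

    def __post_init__(self) -> None:
        total = sum(h.count for h in self.haplotypes)
        if total != self.n:
            raise ValueError(f"haplotype counts sum to {total}, expected {self.n}")

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]

    @property
    def hd(self) -> float:
        return haplotype_diversity(self.counts, self.n)

    def membership(self) -> dict[str, str]:
        return {s: h.id for h in self.haplotypes for s in h.members}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "haplotype": [h.id for h in self.haplotypes],
            "count": self.counts,
            "members": [",".join(h.members) for h in self.haplotypes],
        })


def haplotype_diversity(counts: list[int] | np.ndarray, n: int) -> float:
    """Unbiased haplotype diversity Hd = (n/(n-1)) * (1 - sum p_i^2)."""
    p = np.asarray(counts, dtype=float) / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def collapse_haplotypes(
    panel: AlignedPanel,
    columns: np.ndarray | list[int] | None = None,
    scope: str = "full_length",
) -> HaplotypeTable:
    """Group identical sequences over a column set into haplotypes.

    Gaps are significant (a deletion allele is its own haplotype state).
    Haplotypes are numbered by descending member count, ties broken by
    first-occurring sample.  A sequence containing ``N`` joins the
    complete-sequence haplotype it matches at every called position
    (closest-complete-match; ties to the larger haplotype); if none is
    compatible it forms its own haplotype.
    """
    if columns is None:
        cols = np.arange(1, panel.length + 1)
    else:
        cols = np.asarray(columns, dtype=int)
    sub = panel.columns(cols)
    n = panel.n_samples

    groups: dict[str, list[int]] = {}
    ambiguous: list[int] = []
    for i in range(n):
        seq = "".join(sub[i])
        if MISSING_BASE in seq:
            ambiguous.append(i)
        else:
            groups.setdefault(seq, []).append(i)

    for i in ambiguous:
        row = sub[i]
        called = row != MISSING_BASE
        best_seq, best_count = None, -1
        for seq, members in groups.items():
            ref = np.array(list(seq), dtype="U1")
            if np.array_equal(row[called], ref[called]) and len(members) > best_count:
                best_seq, best_count = seq, len(members)
        if best_seq is None:
            groups["".join(row)] = [i]
            logger.warning("sample %s has no complete match; kept as its own haplotype",
                           panel.sample_ids[i])
        else:
            groups[best_seq].append(i)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    prefix = "CDS_Hap" if scope == "cds" else "Hap"
    haps = [
        Haplotype(f"{prefix}_{k}", seq, [panel.sample_ids[i] for i in sorted(members)])
        for k, (seq, members) in enumerate(ordered, 1)
    ]
    ht = HaplotypeTable(scope, haps, n)
    logger.info("%s: %d haplotypes, Hd=%.4f", scope, len(haps), ht.hd)
    return ht


def map_haplotypes(full: HaplotypeTable, cds: HaplotypeTable) -> dict[str, str]:
    """Map each full-length haplotype to the CDS haplotype its members
    fall in.  Raises if the CDS partition does not refine the full one."""
    cds_of = cds.membership()
    mapping: dict[str, str] = {}
    for h in full.haplotypes:
        targets = {cds_of[s] for s in h.members}
        if len(targets) != 1:
            raise ValueError(f"full-length haplotype {h.id} spans CDS haplotypes {sorted(targets)}")
        mapping[h.id] = targets.pop()
    return mapping


def haplotype_report(full: HaplotypeTable, cds: HaplotypeTable) -> pd.DataFrame:
    """Publication-style membership table: haplotype, count, CDS haplotype,
    member lines."""
    mapping = map_haplotypes(full, cds)
    df = full.to_dataframe()
    df.insert(2, "cds_haplotype", [mapping[h] for h in df["haplotype"]])
    return df


# ---------------------------------------------------------------------------
# protein haplotypes
# ---------------------------------------------------------------------------

@dataclass
class ProteinVariant:
    position: int  # 1-based residue on the longest (no-deletion) protein
    change: str    # e.g. "K45N", "delE120", "del(ED)120-121", "complex120"

    def span(self) -> tuple[int, int]:
        if "-" in self.change.split("del")[-1] and "del(" in self.change:
            inner = self.change.split(")")[-1]
            a, b = inner.split("-")
            return int(a), int(b)
        return self.position, self.position


@dataclass
class ProteinHaplotype:
    id: str
    cds_haplotype: str
    sequence: str
    members: list[str]
    variants: list[ProteinVariant] = field(default_factory=list)
    frameshift: bool = False

    @property
    def count(self) -> int:
        return len(self.members)


def translate_cds_haplotypes(cds_table: HaplotypeTable, model: GeneModel) -> list[ProteinHaplotype]:
    """Translate each CDS haplotype to a protein and list its differences
    from the longest (no-deletion) protein allele.

    Residue coordinates are reported against the longest protein.  The
    column-synchronised scan assumes in-frame indels occupy whole-codon
    windows of the reference allele (true of the alignments this pipeline
    targets); partial-codon overlaps are recorded as ``complex``.
    A haplotype whose ungapped CDS length is not a multiple of 3 is
    translated to its first stop and flagged as a frameshift.
    """
    # reference = haplotype with most called (non-gap) bases
    ref_hap = max(cds_table.haplotypes, key=lambda h: len(h.sequence.replace(GAP, "")))
    ref_seq = np.array(list(ref_hap.sequence), dtype="U1")
    ref_nongap_cols = np.flatnonzero(ref_seq != GAP)
    ref_protein = translate_cds(ref_hap.sequence, model.strand)
    if ref_protein.endswith("*"):
        ref_protein = ref_protein[:-1]

    proteins: list[ProteinHaplotype] = []
    for k, hap in enumerate(cds_table.haplotypes, 1):
        seq = np.array(list(hap.sequence), dtype="U1")
        ungapped = hap.sequence.replace(GAP, "")
        frameshift = len(ungapped) % 3 != 0
        if frameshift:
            aa = translate_cds(ungapped[: 3 * (len(ungapped) // 3)], model.strand)
            aa = aa.split("*")[0]
            logger.warning("CDS haplotype %s is frameshifted; translated to first stop", hap.id)
        else:
            aa = translate_cds(ungapped, model.strand)
            if aa.endswith("*"):
                aa = aa[:-1]
        variants: list[ProteinVariant] = []
        if not frameshift and hap is not ref_hap:
            variants = _diff_against_reference(seq, ref_seq, ref_nongap_cols, ref_protein, model.strand)
        proteins.append(ProteinHaplotype(
            id=f"Protein_{k}", cds_haplotype=hap.id, sequence=aa,
            members=list(hap.members), variants=variants, frameshift=frameshift,
        ))
    return proteins


def _diff_against_reference(seq, ref_seq, ref_nongap_cols, ref_protein, strand) -> list[ProteinVariant]:
    variants: list[ProteinVariant] = []
    pending_del: list[int] = []  # consecutive deleted residue indices

    def flush_dels():
        if not pending_del:
            return
        a, b = pending_del[0], pending_del[-1]
        residues = ref_protein[a - 1:b]
        if a == b:
            variants.append(ProteinVariant(a, f"del{residues}{a}"))
        else:
            variants.append(ProteinVariant(a, f"del({residues}){a}-{b}"))
        pending_del.clear()

    for codon_i in range(len(ref_protein)):
        cols = ref_nongap_cols[3 * codon_i: 3 * codon_i + 3]
        sample_bases = "".join(seq[cols])
        n_bases = len(sample_bases.replace(GAP, ""))
        if n_bases == 3:
            flush_dels()
            aa = translate_cds(sample_bases, strand)
            if aa != ref_protein[codon_i]:
                variants.append(ProteinVariant(
                    codon_i + 1, f"{ref_protein[codon_i]}{codon_i + 1}{aa}"))
        elif n_bases == 0:
            pending_del.append(codon_i + 1)
        else:
            flush_dels()
            variants.append(ProteinVariant(codon_i + 1, f"complex{codon_i + 1}"))
    flush_dels()
    return variants


def domain_overlap(
    proteins: list[ProteinHaplotype],
    domain_intervals: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Intersect every protein variant with configured domain intervals
    (1-based closed residue coordinates on the reference protein)."""
    rows = []
    for p in proteins:
        for v in p.variants:
            a, b = v.span()
            for dom, (lo, hi) in domain_intervals.items():
                rows.append({
                    "protein": p.id, "cds_haplotype": p.cds_haplotype,
                    "variant": v.change, "position": v.position,
                    "domain": dom, "domain_start": lo, "domain_end": hi,
                    "overlaps": not (b < lo or a > hi),
                })
    return pd.DataFrame(rows, columns=["protein", "cds_haplotype", "variant", "position",
                                       "domain", "domain_start", "domain_end", "overlaps"])


def write_protein_fasta(proteins: list[ProteinHaplotype], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.cds_haplotype} n={p.count}\n{p.sequence}\n")
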