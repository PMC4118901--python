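"""Core data model and file I/O.

Holds the aligned sequence panel, the gene-structure annotation, the
phenotype table and the population-structure (Q) matrix, together with the
readers and writers for the plain-text formats the pipeline consumes:
FASTA alignments, YAML gene models, CSV phenotypes and TSV matrices.

Coordinates are 1-based inclusive alignment columns throughout, matching
the convention of locus-scale resequencing studies ("between sites
979-1793 bp").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("genediv")

#: residues allowed in an aligned panel row
ALPHABET = frozenset("ACGTN-")
GAP = "-"
MISSING_BASE = "N"

REGION_KINDS = ("promoter", "exon", "intron", "utr5", "utr3")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger for CLI use (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# AlignedPanel
# ---------------------------------------------------------------------------

@dataclass
class AlignedPanel:
    """A gapped multiple sequence alignment of one locus across inbred lines.

    The panel is the substrate of every statistic downstream.  Rows are
    haploid haplotypes (inbred lines are treated as homozygous); the
    optional reference row is annotation-only and excluded from all
    statistics unless it is listed among ``sample_ids``.

    Attributes
    ----------
    sample_ids
        Unique line names, one per row.
    rows
        ``(N, L)`` array of single characters over ``{A,C,G,T,N,-}``.
    reference_id, reference_seq
        Optional reference row (e.g. the B73 allele used to anchor the
        annotation), kept separate from the samples.
    """

    sample_ids: list[str]
    rows: np.ndarray
    reference_id: str | None = None
    reference_seq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype="U1")
        if self.rows.ndim != 2:
            raise ValueError("rows must be a 2-D character array")
        if len(self.sample_ids) != self.rows.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.rows.shape[0]} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
        if self.n_samples < 2:
            raise ValueError("an aligned panel needs at least 2 samples")
        bad = set(np.unique(self.rows)) - ALPHABET
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        if self.reference_seq is not None:
            self.reference_seq = np.asarray(self.reference_seq, dtype="U1")
            if self.reference_seq.shape != (self.length,):
                raise ValueError("reference length differs from alignment length")

    @property
    def n_samples(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def columns(self, positions: Sequence[int]) -> np.ndarray:
        """Sub-alignment restricted to 1-based column ``positions``."""
        idx = np.asarray(positions, dtype=int) - 1
        return self.rows[:, idx]

    def sequence(self, sample_id: str) -> str:
        return "".join(self.rows[self.sample_ids.index(sample_id)])


def read_alignment(path: str | Path, reference_id: str | None = None) -> AlignedPanel:
    """Read a pre-aligned FASTA file into an :class:`AlignedPanel`.

    Sequences are uppercased and validated; ragged record lengths are a
    hard error naming the offending record.  When ``reference_id`` matches
    a record name, that record is held out as the annotation-only
    reference row.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    length = len(records[0].seq)
    ids, seqs = [], []
    ref_seq = None
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) != length:
            raise ValueError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}: "
                "input must be a flush multiple alignment"
            )
        if reference_id is not None and rec.id == reference_id:
            ref_seq = np.array(list(seq), dtype="U1")
            continue
        ids.append(rec.id)
        seqs.append(list(seq))
    if reference_id is not None and ref_seq is None:
        raise ValueError(f"reference {reference_id!r} not found in {path}")
    panel = AlignedPanel(ids, np.array(seqs, dtype="U1"), reference_id, ref_seq)
    logger.info("read alignment %s: %d samples x %d columns", path, panel.n_samples, panel.length)
    return panel


def write_alignment(panel: AlignedPanel, path: str | Path) -> None:
    """Write a panel (reference row first, if any) as FASTA."""
    records = []
    if panel.reference_id is not None and panel.reference_seq is not None:
        records.append(SeqRecord(Seq("".join(panel.reference_seq)), id=panel.reference_id, description=""))
    for sid, row in zip(panel.sample_ids, panel.rows):
        records.append(SeqRecord(Seq("".join(row)), id=sid, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    name: str
    kind: str  # promoter | exon | intron | utr5 | utr3
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"region {self.name!r}: unknown kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"region {self.name!r}: bad coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class GeneModel:
    """Ordered, non-overlapping named regions plus the CDS frame.

    ``cds_region_names`` lists, in order, the exons whose concatenation is
    the coding sequence; its total length must be a multiple of 3.
    """

    regions: list[Region]
    cds_region_names: list[str]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(f"regions {a.name!r} and {b.name!r} overlap")
        self.regions = ordered
        by_name = {r.name: r for r in self.regions}
        for name in self.cds_region_names:
            if name not in by_name:
                raise ValueError(f"CDS region {name!r} not among regions")
        if self.cds_region_names:
            cds_len = sum(by_name[n].length for n in self.cds_region_names)
            if cds_len % 3 != 0:
                raise ValueError(f"CDS length {cds_len} is not a multiple of 3")

    @property
    def length(self) -> int:
        return max(r.end for r in self.regions)

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def cds_columns(self) -> np.ndarray:
        """CDS alignment columns, 1-based, in translation order on '+'."""
        cols = np.concatenate([self.region(n).positions for n in self.cds_region_names])
        return cols

    def region_of(self, position: int) -> str | None:
        for r in self.regions:
            if r.start <= position <= r.end:
                return r.name
        return None


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a gene model from a YAML config.

    Schema::

        strand: "+"
        cds_regions: [exon1, exon2, exon3]
        regions:
          - {name: promoter, kind: promoter, start: 1, end: 520}
          - {name: exon1, kind: exon, start: 521, end: 1144}
          ...
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    regions = [Region(r["name"], r["kind"], int(r["start"]), int(r["end"])) for r in cfg["regions"]]
    model = GeneModel(regions, list(cfg.get("cds_regions", [])), cfg.get("strand", "+"))
    for r in model.regions:
        logger.info("region %-10s %-8s %5d..%-5d (%d bp)", r.name, r.kind, r.start, r.end, r.length)
    return model


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    cfg = {
        "strand": model.strand,
        "cds_regions": list(model.cds_region_names),
        "regions": [
            {"name": r.name, "kind": r.kind, "start": int(r.start), "end": int(r.end)}
            for r in model.regions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# PhenotypeTable
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-line trait measurements, optionally with replicates.

    ``data`` has one row per (line, replicate) with a ``line`` column, an
    optional integer ``replicate`` column and one numeric column per trait.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "line" not in self.data.columns:
            raise ValueError("phenotype table needs a 'line' column")
        for t in self.traits:
            col = self.data[t]
            if not pd.api.types.is_numeric_dtype(col):
                bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(f"non-numeric value in trait {t!r} at row {row}")
            finite = np.isfinite(col.dropna().to_numpy(dtype=float))
            if not finite.all():
                raise ValueError(f"non-finite value in trait {t!r}")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("line", "replicate")]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["line"]))

    def line_means(self) -> pd.DataFrame:
        """Per-line trait means (association runs on these)."""
        return self.data.groupby("line", sort=False)[self.traits].mean()

    def restrict(self, sample_ids: Iterable[str]) -> "PhenotypeTable":
        keep = set(sample_ids)
        dropped = [s for s in self.sample_ids if s not in keep]
        if dropped:
            logger.warning("dropping %d phenotype lines absent from panel: %s", len(dropped), dropped[:5])
        return PhenotypeTable(self.data[self.data["line"].isin(keep)].reset_index(drop=True))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    for c in df.columns:
        if c in ("line", "replicate"):
            continue
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            bad = df[c][pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            raise ValueError(
                f"non-numeric trait value in column {c!r}, row {bad.index[0]}: {bad.iloc[0]!r}"
            ) from exc
    pt = PhenotypeTable(df)
    logger.info("read phenotypes %s: %d rows, %d traits", path, len(df), len(pt.traits))
    return pt


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    pt.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QMatrix
# ---------------------------------------------------------------------------

@dataclass
class QMatrix:
    """Per-sample admixture proportions used as GLM covariates.

    Accepts either the full K-column encoding (rows sum to 1) or the
    K-1-column encoding (rows sum to <= 1).  The Q matrix is always an
    input — estimated upstream (e.g. by STRUCTURE), never computed here.
    """

    sample_ids: list[str]
    values: np.ndarray  # (N, K) or (N, K-1)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("Q matrix rows do not match sample ids")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("admixture proportions must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if np.any(sums > 1 + 1e-6):
            bad = int(np.argmax(sums))
            raise ValueError(
                f"Q row for {self.sample_ids[bad]!r} sums to {sums[bad]:.4f} > 1"
            )

    @property
    def k(self) -> int:
        """Number of subpopulations implied by the encoding."""
        sums = self.values.sum(axis=1)
        full = np.allclose(sums, 1.0, atol=1e-6)
        return self.values.shape[1] if full else self.values.shape[1] + 1

    def design_columns(self) -> np.ndarray:
        """Covariate columns for regression: K-1 columns (drop the last
        when rows sum to one) to avoid collinearity with the intercept."""
        sums = self.values.sum(axis=1)
        if self.values.shape[1] > 1 and np.allclose(sums, 1.0, atol=1e-6):
            return self.values[:, :-1]
        if self.values.shape[1] == 1 and np.allclose(sums, 1.0, atol=1e-6):
            # K=1: no structure information at all
            return np.empty((self.values.shape[0], 0))
        return self.values

    def restrict(self, sample_ids: Sequence[str]) -> "QMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return QMatrix(list(sample_ids), self.values[idx])


def read_qmatrix(path: str | Path) -> QMatrix:
    df = pd.read_csv(path, sep=None, engine="python")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    q = QMatrix(sample_ids, values)
    logger.info("read Q matrix %s: %d samples, %d columns (K=%d)", path, len(sample_ids), values.shape[1], q.k)
    return q


def write_qmatrix(q: QMatrix, path: str | Path) -> None:
    df = pd.DataFrame(q.values, columns=[f"Q{i+1}" for i in range(q.values.shape[1])])
    df.insert(0, "line", q.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with a deterministic column order."""
    df.to_csv(path, sep="\t", index=False)
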