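"""Readers and writers for the pipeline's external formats.

Formats handled here:

* FASTA (genomes, mature/hairpin miRNA sequences) via Biopython;
* BED (0-based half-open genomic intervals);
* TSV count tables (entity id x sample, non-negative integer counts);
* tab-delimited multi-species gapped 3'UTR alignments
  (gene id, species id, aligned sequence; one block per gene);
* gene-set annotation TSV (set id, gene id).

Every reader validates strictly and every reader/writer pair is a lossless
round trip on valid inputs. Genomic intervals are 0-based half-open
throughout; transcript-side sequences are canonicalised to RNA (T -> U).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import GAP, RNA_ALPHABET, to_rna, validate_alphabet


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass(frozen=True)
class UTRAlignmentBlock:
    """Gapped multi-species alignment of one gene's 3'UTR.

    ``rows`` preserves file order; ``ref_coord_map[i]`` gives the alignment
    column of the i-th ungapped base of the reference species row.
    """

    gene_id: str
    rows: tuple[tuple[str, str], ...]  # (species id, gapped RNA sequence)
    ref_species: str

    def __post_init__(self):
        if not self.rows:
            raise FormatError(f"alignment block {self.gene_id!r} has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows for gene {self.gene_id!r}: "
                              f"lengths {sorted(lengths)}")
        species = [sp for sp, _ in self.rows]
        if len(set(species)) != len(species):
            raise FormatError(f"duplicate species row in block {self.gene_id!r}")
        if self.ref_species not in species:
            raise FormatError(f"block {self.gene_id!r} lacks reference species row "
                              f"{self.ref_species!r}")
        validate_alphabet(self.ref_seq, RNA_ALPHABET, what=f"reference row of {self.gene_id!r}",
                          allow_gap=True)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sp for sp, _ in self.rows)

    @property
    def ref_seq(self) -> str:
        return dict(self.rows)[self.ref_species]

    def row(self, species: str) -> str:
        try:
            return dict(self.rows)[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in block {self.gene_id!r}") from None

    @property
    def ref_coord_map(self) -> dict[int, int]:
        """Ungapped 0-based reference position -> alignment column."""
        return {i: col for i, col in enumerate(
            c for c, ch in enumerate(self.ref_seq) if ch != GAP)}

    @property
    def ref_ungapped(self) -> str:
        return self.ref_seq.replace(GAP, "")


@dataclasses.dataclass
class CountTable:
    """Non-negative integer counts (entity x sample) plus per-sample
    mapped-read totals.

    Totals are library mapped-read totals supplied independently; they are
    not required to equal column sums of the assigned counts.
    """

    counts: pd.DataFrame  # index = entity ids, columns = sample ids
    totals: dict[str, int]

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate entity id {dup!r} in count table")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative count in count table")
        missing = set(self.counts.columns) - set(self.totals)
        if missing:
            raise FormatError(f"samples missing from totals: {sorted(missing)}")

    @property
    def entities(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, *, as_rna: bool = False) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} mapping.

    Multi-line records and either T or U are accepted; with ``as_rna`` the
    sequences are canonicalised to ACGU.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        out[rec.id] = to_rna(seq) if as_rna else seq
    return out


def write_fasta(path: str | Path, seqs: Mapping[str, str], *, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read a 6-column BED file: (chrom, start, end, name, strand).

    Coordinates are 0-based half-open, BED's native convention.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected >=6 BED columns")
        chrom, start, end, name, _score, strand = fields[:6]
        start_i, end_i = int(start), int(end)
        if not 0 <= start_i < end_i:
            raise FormatError(f"{path}:{lineno}: invalid interval [{start_i}, {end_i})")
        if strand not in "+-":
            raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
        rows.append((chrom, start_i, end_i, name, strand))
    return rows


def write_bed(path: str | Path, intervals: Iterable[tuple[str, int, int, str, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Count tables

def read_counts(path: str | Path, totals: Mapping[str, int]) -> CountTable:
    """Read a TSV count table (header = sample ids, first column = entity id).

    Counts must parse as non-negative integers; duplicate entity rows and
    samples absent from ``totals`` are rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty count table")
    header = lines[0].split("\t")
    samples = header[1:]
    if not samples:
        raise FormatError(f"{path}: no sample columns")
    ids, data = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} columns, "
                              f"got {len(fields)}")
        row = []
        for sample, val in zip(samples, fields[1:]):
            try:
                count = int(val)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer count {val!r} "
                                  f"for sample {sample!r}") from None
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            row.append(count)
        ids.append(fields[0])
        data.append(row)
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FormatError(f"{path}: duplicate entity id {dup!r}")
    counts = pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=samples)
    missing = [s for s in samples if s not in totals]
    if missing:
        raise FormatError(f"{path}: samples missing from totals: {missing}")
    return CountTable(counts=counts, totals={s: int(totals[s]) for s in samples})


def write_counts(path: str | Path, table: CountTable) -> None:
    table.counts.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# Aligned UTR blocks

def read_utr_alignments(path: str | Path, *, ref_species: str | None = None
                        ) -> list[UTRAlignmentBlock]:
    """Read a tab-delimited aligned-UTR file into alignment blocks.

    Lines are (gene id, species id, gapped sequence), grouped by gene id.
    T is transliterated to U. The reference species defaults to the species
    of the first row of each block (files conventionally list it first).
    """
    path = Path(path)
    groups: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        gene, species, seq = fields
        groups.setdefault(gene, []).append((species, to_rna(seq)))
    blocks = []
    for gene, rows in groups.items():
        ref = ref_species if ref_species is not None else rows[0][0]
        blocks.append(UTRAlignmentBlock(gene_id=gene, rows=tuple(rows), ref_species=ref))
    return blocks


def write_utr_alignments(path: str | Path, blocks: Iterable[UTRAlignmentBlock]) -> None:
    with open(path, "w") as fh:
        for block in blocks:
            for species, seq in block.rows:
                fh.write(f"{block.gene_id}\t{species}\t{seq}\n")


# ---------------------------------------------------------------------------
# Gene sets

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (set id, gene id) TSV into {set id: gene set}."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        set_id, gene = fields
        sets.setdefault(set_id, set()).add(gene)
    return sets


def write_gene_sets(path: str | Path, sets: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            for gene in sorted(sets[set_id]):
                fh.write(f"{set_id}\t{gene}\n")
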