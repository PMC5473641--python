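"""Multiple alignments with reference-species coordinate mapping.

Columns are stored as a (species x column) byte-code matrix over the
alphabet {A,C,G,T,-,N}.  One species is designated the reference; every
column where the reference row is ungapped carries a 0-based reference
coordinate (MAF semantics).  Gaps and N are missing data for all
likelihood computations.  MAF and multi-FASTA round-trip through
Bio.AlignIO.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["MultipleAlignment", "read_maf", "read_fasta", "GAP", "NCODE", "encode", "decode"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
GAP, NCODE = 4, 5
_DECODE = np.frombuffer(b"ACGT-N", dtype="S1")

_LUT = np.full(256, 255, dtype=np.uint8)
for ch, co in _CODE.items():
    _LUT[ord(ch)] = co
    _LUT[ord(ch.lower())] = co


def encode(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _LUT[a]
    if np.any(codes == 255):
        bad = chr(a[np.argmax(codes == 255)])
        raise ValueError(f"character {bad!r} outside alphabet ACGT-N")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


class MultipleAlignment:
    """One alignment block: species rows over {A,C,G,T,-,N}.

    Parameters
    ----------
    species : ordered row names (unique).
    matrix : uint8 array (n_species, n_columns) of base codes.
    reference : name of the reference species (defaults to the first row).
    chrom, ref_start : reference coordinate of the first ungapped
        reference column (0-based).
    """

    def __init__(
        self,
        species: Sequence[str],
        matrix: np.ndarray,
        reference: str | None = None,
        chrom: str = "chr1",
        ref_start: int = 0,
    ):
        self.species = list(species)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        self.matrix = np.asarray(matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.species):
            raise ValueError("matrix shape must be (n_species, n_columns)")
        self.reference = reference if reference is not None else self.species[0]
        if self.reference not in self.species:
            raise ValueError(f"reference {self.reference!r} not a row")
        self.chrom = chrom
        self.ref_start = int(ref_start)
        self._ref_positions: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    @classmethod
    def from_strings(cls, rows: dict[str, str], **kw) -> "MultipleAlignment":
        lens = {len(s) for s in rows.values()}
        if len(lens) > 1:
            raise ValueError("rows differ in length")
        mat = np.vstack([encode(s) for s in rows.values()]) if rows else np.zeros((0, 0), np.uint8)
        return cls(list(rows), mat, **kw)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, species: str) -> np.ndarray:
        return self.matrix[self.species.index(species)]

    def row_string(self, species: str) -> str:
        return decode(self.row(species))

    @property
    def ref_positions(self) -> np.ndarray:
        """Per-column 0-based reference coordinate; -1 where the reference is gapped."""
        if self._ref_positions is None:
            ref = self.row(self.reference)
            ungapped = ref != GAP
            pos = np.cumsum(ungapped) - 1 + self.ref_start
            pos[~ungapped] = -1
            self._ref_positions = pos.astype(np.int64)
        return self._ref_positions

    @property
    def ref_end(self) -> int:
        p = self.ref_positions
        p = p[p >= 0]
        return int(p[-1]) + 1 if len(p) else self.ref_start

    # ------------------------------------------------------------------ #
    def column_slice(self, start: int, end: int) -> "MultipleAlignment":
        sub = MultipleAlignment(
            self.species, self.matrix[:, start:end], self.reference, self.chrom, 0
        )
        p = self.ref_positions[start:end]
        p = p[p >= 0]
        sub.ref_start = int(p[0]) if len(p) else 0
        return sub

    def ref_interval_columns(self, start: int, end: int) -> np.ndarray:
        """Column indices whose reference coordinate lies in [start, end)."""
        p = self.ref_positions
        return np.flatnonzero((p >= start) & (p < end))

    def extract_ref_interval(self, start: int, end: int) -> "MultipleAlignment":
        """Columns spanning reference interval [start, end), including any
        interior columns where the reference is gapped (insertions)."""
        cols = self.ref_interval_columns(start, end)
        if len(cols) == 0:
            raise ValueError(f"no columns map to [{start},{end}) on {self.chrom}")
        lo, hi = int(cols[0]), int(cols[-1]) + 1
        sub = MultipleAlignment(
            self.species, self.matrix[:, lo:hi], self.reference, self.chrom, start
        )
        return sub

    def subset_species(self, names: Iterable[str]) -> "MultipleAlignment":
        names = list(names)
        idx = [self.species.index(n) for n in names]
        ref = self.reference if self.reference in names else names[0]
        sub = MultipleAlignment(names, self.matrix[idx], ref, self.chrom, self.ref_start)
        return sub

    # ------------------------------------------------------------------ #
    def _records(self):
        for sp in self.species:
            yield SeqRecord(Seq(self.row_string(sp)), id=sp, description="")

    def write_fasta(self, path) -> None:
        SeqIO.write(self._records(), path, "fasta")

    def write_maf(self, path) -> None:
        recs = []
        for sp in self.species:
            rec = SeqRecord(Seq(self.row_string(sp)), id=f"{sp}.{self.chrom}")
            row = self.row(sp)
            size = int(np.sum(row != GAP))
            start = self.ref_start if sp == self.reference else 0
            rec.annotations = {
                "start": start,
                "size": size,
                "strand": 1,
                "srcSize": max(self.ref_end, size),
            }
            recs.append(rec)
        msa = MultipleSeqAlignment(recs)
        with open(path, "w") as fh:
            AlignIO.write([msa], fh, "maf")


def _from_msa(msa, reference: str | None = None) -> MultipleAlignment:
    rows: dict[str, str] = {}
    chrom, ref_start = "chr1", 0
    first = None
    for rec in msa:
        name = rec.id
        if "." in name:
            name, src_chrom = name.split(".", 1)
        else:
            src_chrom = "chr1"
        if first is None:
            first = name
            chrom = src_chrom
            ref_start = int(rec.annotations.get("start", 0))
        rows[name] = str(rec.seq).upper()
    aln = MultipleAlignment.from_strings(
        rows, reference=reference or first, chrom=chrom, ref_start=ref_start
    )
    return aln


def read_maf(path, reference: str | None = None) -> list[MultipleAlignment]:
    """Read a MAF file into a list of alignment blocks (reference row first)."""
    return [_from_msa(msa, reference) for msa in AlignIO.parse(path, "maf")]


def read_fasta(path, reference: str | None = None, chrom: str = "chr1", ref_start: int = 0) -> MultipleAlignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    return MultipleAlignment.from_strings(
        rows, reference=reference or next(iter(rows)), chrom=chrom, ref_start=ref_start
    )
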