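"""Alignment utilities: MAF slicing, MAF-to-FASTA stitching, profile merging,
column trimming, and pairwise p-distances.

Coordinates are 0-based half-open throughout.  MAF rows are stored exactly as
in the format (start/size on the row's own strand, with srcSize allowing
conversion to forward coordinates); the reference species of a block is its
first row.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RegionSpec:
    """Named interval on a named sequence (reference coordinates)."""

    sequence_id: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.name!r}: [{self.start}, {self.end})")


@dataclass
class MafRow:
    src: str
    start: int
    size: int
    strand: int        # +1 / -1
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]


@dataclass
class MafBlock:
    rows: list[MafRow]
    score: float | None = None

    def __post_init__(self):
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("MAF block rows differ in aligned width")
        for r in self.rows:
            ungapped = sum(1 for c in r.text if c != "-")
            if ungapped != r.size:
                raise ValueError(f"row {r.src}: size {r.size} != ungapped length {ungapped}")

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    @property
    def reference(self) -> MafRow:
        return self.rows[0]


def read_maf(handle) -> list[MafBlock]:
    """Parse MAF blocks from a text handle or path."""
    from Bio import AlignIO

    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle)
        close = True
    try:
        blocks = []
        for msa in AlignIO.parse(handle, "maf"):
            rows = []
            for rec in msa:
                ann = rec.annotations
                rows.append(MafRow(
                    src=rec.id, start=int(ann["start"]), size=int(ann["size"]),
                    strand=int(ann["strand"]), src_size=int(ann["srcSize"]),
                    text=str(rec.seq),
                ))
            blocks.append(MafBlock(rows, score=msa.annotations.get("score")))
        return blocks
    finally:
        if close:
            handle.close()


def write_maf(blocks: list[MafBlock], handle) -> None:
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("##maf version=1\n\n")
        for b in blocks:
            handle.write(f"a score={b.score if b.score is not None else 0.0}\n")
            for r in b.rows:
                strand = "+" if r.strand >= 0 else "-"
                handle.write(f"s {r.src} {r.start} {r.size} {strand} {r.src_size} {r.text}\n")
            handle.write("\n")
    finally:
        if close:
            handle.close()


@dataclass
class MultipleAlignment:
    """Rows of equal length over unique ids; gaps are '-'."""

    ids: list[str]
    rows: list[str]
    column_map: list[int] | None = None   # original column indices, if trimmed

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def slice_columns(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment(list(self.ids), [r[start:end] for r in self.rows])

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), np.uint8).reshape(
            len(self.rows), -1) if self.rows else np.empty((0, 0), np.uint8)

    def write_fasta(self, handle) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(r), id=i, description="")
                   for i, r in zip(self.ids, self.rows)]
        if isinstance(handle, (str, bytes)):
            SeqIO.write(records, handle, "fasta")
        else:
            SeqIO.write(records, handle, "fasta")

    @classmethod
    def read_fasta(cls, handle) -> "MultipleAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(handle, "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)


# ---------------------------------------------------------------------------
# MAF operations
# ---------------------------------------------------------------------------

def _gap_aware_columns(text: str, offset_lo: int, offset_hi: int) -> tuple[int, int]:
    """Columns spanned by the ungapped offsets [offset_lo, offset_hi)."""
    nongap = np.frombuffer(text.encode(), np.uint8) != ord("-")
    positions = np.nonzero(nongap)[0]
    return int(positions[offset_lo]), int(positions[offset_hi - 1]) + 1


def extract_maf_region(blocks, region: RegionSpec) -> list[MafBlock]:
    """Clip blocks to a reference-coordinate region.

    The reference is the block's first row and must match
    ``region.sequence_id`` on the forward strand; per-row starts and sizes
    are recomputed exactly for the retained columns.
    """
    out = []
    for block in blocks:
        ref = block.reference
        if ref.src != region.sequence_id:
            continue
        if ref.strand < 0:
            raise ValueError("reference rows must be on the forward strand")
        lo = max(ref.start, region.start)
        hi = min(ref.start + ref.size, region.end)
        if lo >= hi:
            continue
        col_lo, col_hi = _gap_aware_columns(ref.text, lo - ref.start, hi - ref.start)
        rows = []
        for r in block.rows:
            before = sum(1 for c in r.text[:col_lo] if c != "-")
            text = r.text[col_lo:col_hi]
            size = sum(1 for c in text if c != "-")
            rows.append(MafRow(r.src, r.start + before, size, r.strand, r.src_size, text))
        out.append(MafBlock(rows, score=block.score))
    return out


def maf_to_fasta(blocks: list[MafBlock], species: list[str]) -> MultipleAlignment:
    """Stitch blocks into one alignment over the requested species.

    Blocks are ordered by the reference row; species missing from a block are
    padded with gaps over that block's width.  Overlapping blocks on the
    reference are a consistency error.
    """
    if not blocks:
        return MultipleAlignment(list(species), ["" for _ in species])
    ordered = sorted(blocks, key=lambda b: b.reference.start)
    prev_end = None
    for b in ordered:
        ref = b.reference
        if prev_end is not None and ref.start < prev_end:
            raise ValueError(
                f"blocks overlap on the reference at {ref.src}:{ref.start}")
        prev_end = ref.start + ref.size
    parts: dict[str, list[str]] = {s: [] for s in species}
    for b in ordered:
        present = {}
        for r in b.rows:
            present.setdefault(r.species, r.text)
        for s in species:
            parts[s].append(present.get(s, "-" * b.width))
    return MultipleAlignment(list(species), ["".join(parts[s]) for s in species])


# ---------------------------------------------------------------------------
# Profile-profile merging
# ---------------------------------------------------------------------------

_MERGE_SYMBOLS = "ACGT-"


def _profile(aln: MultipleAlignment) -> np.ndarray:
    """Per-column frequency of A, C, G, T, gap (other symbols count as gap)."""
    arr = aln.to_array()
    prof = np.zeros((aln.n_columns, 5))
    for k, sym in enumerate(b"ACGT"):
        prof[:, k] = (arr == sym).mean(axis=0)
    prof[:, 4] = 1.0 - prof[:, :4].sum(axis=1)
    return prof


def merge_alignments(
    a: MultipleAlignment,
    b: MultipleAlignment,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_vs_base: float = -1.0,
    gap_penalty: float = 2.0,
) -> MultipleAlignment:
    """Global profile-profile alignment of two alignments (disjoint id sets).

    Columns of each input are kept intact as units; the column-pair score is
    the expected substitution score between the two columns' residue
    distributions, and new gap columns cost ``gap_penalty`` each (linear).
    """
    if not a.ids or not b.ids:
        raise ValueError("both alignments must be nonempty")
    if set(a.ids) & set(b.ids):
        raise ValueError(f"id collision: {sorted(set(a.ids) & set(b.ids))}")

    m5 = np.full((5, 5), mismatch)
    np.fill_diagonal(m5, match)
    m5[4, :] = gap_vs_base
    m5[:, 4] = gap_vs_base
    m5[4, 4] = 0.0
    pa, pb = _profile(a), _profile(b)
    S = pa @ m5 @ pb.T
    wa, wb = pa.shape[0], pb.shape[0]

    g = gap_penalty
    H = np.empty((wa + 1, wb + 1))
    H[0, :] = -g * np.arange(wb + 1)
    H[:, 0] = -g * np.arange(wa + 1)
    idx = np.arange(1, wb + 1, dtype=float)
    for i in range(1, wa + 1):
        H0 = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] - g)
        base = np.maximum.accumulate(np.concatenate(([H[i, 0]], H0[:-1] + idx[:-1] * g)))
        H[i, 1:] = np.maximum(H0, base - idx * g)

    # traceback
    i, j = wa, wb
    take: list[tuple[int, int]] = []  # (-1 means gap)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(H[i, j], H[i - 1, j - 1] + S[i - 1, j - 1]):
            take.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(H[i, j], H[i - 1, j] - g):
            take.append((i - 1, -1))
            i -= 1
        else:
            take.append((-1, j - 1))
            j -= 1
    take.reverse()

    rows_a = [[] for _ in a.ids]
    rows_b = [[] for _ in b.ids]
    for ca, cb in take:
        for r, out in zip(a.rows, rows_a):
            out.append(r[ca] if ca >= 0 else "-")
        for r, out in zip(b.rows, rows_b):
            out.append(r[cb] if cb >= 0 else "-")
    return MultipleAlignment(
        list(a.ids) + list(b.ids),
        ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b],
    )


# ---------------------------------------------------------------------------
# Trimming and distances
# ---------------------------------------------------------------------------

def trim_columns(aln: MultipleAlignment, max_gap_fraction: float = 0.8) -> MultipleAlignment:
    """Drop columns whose gap fraction exceeds the threshold.

    The surviving original column indices are retained in ``column_map`` for
    coordinate back-translation.  Removing every column returns an empty
    alignment (callers are expected to treat that as a warning condition).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    arr = aln.to_array()
    gap_frac = (arr == ord("-")).mean(axis=0) if arr.size else np.empty(0)
    keep = np.nonzero(gap_frac <= max_gap_fraction)[0]
    rows = []
    for r in aln.rows:
        buf = np.frombuffer(r.encode(), np.uint8)[keep]
        rows.append(buf.tobytes().decode())
    return MultipleAlignment(list(aln.ids), rows, column_map=[int(k) for k in keep])


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray                      # square, symmetric; nan = undefined
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (excluding the diagonal), nan included."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_tsv(self, handle) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(handle, sep="\t", float_format="%.6g")


def pairwise_p_distance(aln: MultipleAlignment) -> DistanceMatrix:
    """Observed proportion of differing nucleotides, pairwise deletion.

    Only columns where both rows hold an unambiguous A/C/G/T are compared
    (gaps and IUPAC ambiguity codes are excluded); pairs with no comparable
    site get a NaN distance and are listed in ``undefined_pairs``.
    """
    if len(aln.ids) < 2:
        raise ValueError("need at least two rows")
    arr = aln.to_array()
    arr = np.where((arr >= ord("a")) & (arr <= ord("z")), arr - 32, arr)
    valid = np.isin(arr, _ACGT)
    n = len(aln.ids)
    out = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                out[i, j] = out[j, i] = np.nan
                undefined.append((aln.ids[i], aln.ids[j]))
            else:
                diff = int((arr[i][both] != arr[j][both]).sum())
                out[i, j] = out[j, i] = diff / m
    return DistanceMatrix(list(aln.ids), out, undefined)
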