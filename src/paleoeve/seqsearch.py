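"""Six-frame translated local-alignment search (tBLASTn-like).

A protein probe is aligned against all six translation frames of a nucleotide
subject with affine-gap Smith-Waterman.  Candidate regions are located by
2-mer word seeding (BLOSUM neighbourhood scoring) and alignment is restricted
to windows around seed clusters; with a permissive seed threshold the search
is provably equivalent to exhaustive per-frame Smith-Waterman (see the
package methods note).  Raw scores are converted to E-values with
Karlin-Altschul statistics computed from the scoring matrix.  Stop codons
translate to ``*`` and are alignable at a strong penalty: premature stops and
frame changes between chained HSPs are the degeneration signal reported by
:func:`annotate_inactivation`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = np.full(256, AA_ALPHABET.index("X"), dtype=np.int64)
for _i, _a in enumerate(AA_ALPHABET):
    _AA_INDEX[ord(_a)] = _i

_NT_VALID = set("ACGTNacgtn")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SearchConfigError(ValueError):
    """Raised when scoring parameters make the statistics unusable."""


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoringMatrix:
    """Protein scoring matrix with affine gap penalties.

    ``gap_open`` is charged once per gap and ``gap_extend`` once per gapped
    position (a gap of length g costs ``gap_open + g * gap_extend``).  All
    pairings with a stop (``*``) score ``stop_score``; aligning through stops
    is allowed because premature stops are the signal being annotated.
    """

    name: str
    scores: np.ndarray           # (24, 24) int
    gap_open: float = 15.0
    gap_extend: float = 2.0
    stop_score: float = -5.0

    def __post_init__(self):
        if self.scores.shape != (24, 24):
            raise ValueError("expected a 24x24 score array over " + AA_ALPHABET)
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("scoring matrix must be symmetric")

    @classmethod
    def blosum45(cls, gap_open: float = 15.0, gap_extend: float = 2.0,
                 stop_score: float = -5.0) -> "ScoringMatrix":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM45")
        arr = np.zeros((24, 24))
        for i, a in enumerate(AA_ALPHABET):
            for j, b in enumerate(AA_ALPHABET):
                arr[i, j] = m[a, b]
        stop = AA_ALPHABET.index("*")
        arr[stop, :] = stop_score
        arr[:, stop] = stop_score
        return cls("BLOSUM45", arr, gap_open, gap_extend, stop_score)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[_AA_INDEX[ord(a)], _AA_INDEX[ord(b)]])

    @property
    def max_pair_score(self) -> float:
        std = [AA_ALPHABET.index(a) for a in AA_ALPHABET[:20]]
        return float(self.scores[np.ix_(std, std)].max())


@dataclass
class SearchParams:
    """Tunable knobs of the translated search.

    With ``seed_threshold <= 1`` and ``min_raw_score >= max pair score + 1``
    the seeded search provably returns the exhaustive Smith-Waterman optimum
    (any alignment above that score must contain a positive-scoring word when
    a single gap costs at least the maximal pair score).  The default
    threshold of 11 is a production setting emulating BLAST word seeding.
    """

    word_size: int = 2
    seed_threshold: float = 12.0
    min_raw_score: float = 16.0
    evalue_max: float | None = 10.0
    window_join: int = 60        # aa gap at which seed clusters split
    window_pad: int | None = None  # aa; default probe length + 20 (sensitive mode)
    band_bucket: int = 16        # aa; diagonal bucket width for fast clustering
    min_cluster_seeds: int = 3   # seeds required to open a banded window
    max_hsps_per_frame: int = 8
    exhaustive: bool = False
    chain_junction_penalty: float = 20.0  # raw-score cost per chained junction
    background_freqs: tuple[float, ...] | None = None  # 20 aa, default uniform
    gapped_scale: float = 0.9    # lambda/K scaling for the gapped regime
    use_gapped_stats: bool = True


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameTranslation:
    """One translated frame with an exact coordinate map to the forward strand."""

    frame: int               # +1..+3, -1..-3
    aa: str
    subject_length: int      # nt

    @property
    def strand(self) -> int:
        return 1 if self.frame > 0 else -1

    def to_forward(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa interval (half-open) to forward-strand nt coordinates."""
        off = abs(self.frame) - 1
        if self.frame > 0:
            return off + 3 * aa_start, off + 3 * aa_end
        return (self.subject_length - off - 3 * aa_end,
                self.subject_length - off - 3 * aa_start)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def six_frame_translate(seq: str) -> list[FrameTranslation]:
    """All six translation frames; codons containing N become X, stops ``*``."""
    bad = sorted({c for c in seq if c not in _NT_VALID})
    if bad:
        raise ValueError(f"illegal nucleotide characters: {bad}")
    from .synthsim import translate_codons

    seq = seq.upper()
    rc = reverse_complement(seq)
    out = []
    for off in range(3):
        out.append(FrameTranslation(off + 1, translate_codons(seq[off:]), len(seq)))
    for off in range(3):
        out.append(FrameTranslation(-(off + 1), translate_codons(rc[off:]), len(seq)))
    return out


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KarlinParams:
    lam: float
    K: float
    H: float
    regime: str  # "ungapped" | "gapped-scaled"


def _score_distribution(matrix: ScoringMatrix, freqs: np.ndarray):
    std = np.arange(20)
    sub = matrix.scores[np.ix_(std, std)].astype(int)
    probs = np.outer(freqs, freqs)
    lo, hi = int(sub.min()), int(sub.max())
    pmf = np.zeros(hi - lo + 1)
    for s, p in zip(sub.ravel(), probs.ravel()):
        pmf[int(s) - lo] += p
    return pmf, lo, hi


def karlin_lambda(matrix: ScoringMatrix, freqs=None) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1."""
    freqs = _background(freqs)
    pmf, lo, hi = _score_distribution(matrix, freqs)
    support = np.arange(lo, hi + 1)
    mean = float(np.dot(pmf, support))
    if mean >= 0 or hi <= 0:
        raise SearchConfigError(
            "expected pair score must be negative and max score positive "
            f"(mean={mean:.3f}, max={hi})")

    def f(lam):
        return float(np.dot(pmf, np.exp(lam * support))) - 1.0

    upper = 1.0
    while f(upper) < 0:
        upper *= 2.0
        if upper > 1e3:
            raise SearchConfigError("failed to bracket Karlin lambda")
    return float(brentq(f, 1e-9, upper, xtol=1e-12))


def karlin_params(matrix: ScoringMatrix, freqs=None, *, gapped_scale: float | None = None,
                  max_terms: int = 120) -> KarlinParams:
    """Karlin-Altschul lambda, K and relative entropy H for ungapped scoring.

    K uses the lattice-case series: sigma accumulates, over convolution powers
    of the pair-score distribution, the terms P(S_k >= 0) + E[exp(lam S_k);
    S_k < 0] weighted 1/k; then K = delta*lam*exp(-2 sigma)/(H (1-exp(-lam
    delta))).  Gapped statistics are approximated by scaling lambda and K by
    ``gapped_scale`` (island estimation is out of scope); E-values carry the
    regime label.
    """
    freqs = _background(freqs)
    lam = karlin_lambda(matrix, freqs)
    pmf, lo, hi = _score_distribution(matrix, freqs)
    support = np.arange(lo, hi + 1)
    nz = support[pmf > 0]
    delta = int(np.gcd.reduce(np.abs(nz[nz != 0]).astype(int)))
    H = float(lam * np.dot(pmf, support * np.exp(lam * support)))

    sigma = 0.0
    conv = pmf.copy()
    conv_lo = lo
    for k in range(1, max_terms + 1):
        s_vals = np.arange(conv_lo, conv_lo + len(conv))
        neg = s_vals < 0
        term = float(conv[~neg].sum() + np.dot(conv[neg], np.exp(lam * s_vals[neg])))
        sigma += term / k
        if term / k < 1e-10:
            break
        conv = np.convolve(conv, pmf)
        conv_lo += lo
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    if gapped_scale is not None:
        return KarlinParams(lam * gapped_scale, K * gapped_scale, H, "gapped-scaled")
    return KarlinParams(lam, K, H, "ungapped")


def _background(freqs):
    if freqs is None:
        return np.full(20, 0.05)
    f = np.asarray(freqs, dtype=float)
    if f.shape != (20,) or abs(f.sum() - 1.0) > 1e-8 or np.any(f < 0):
        raise SearchConfigError("background frequencies must be 20 values summing to 1")
    return f


def estimate_evalue(raw_score: float, probe_length: int, subject_length: int,
                    kp: KarlinParams) -> tuple[float, float]:
    """(E-value, bit score) for a raw score in an m x n search space."""
    if probe_length <= 0 or subject_length <= 0:
        raise ValueError("search-space dimensions must be positive")
    bit = (kp.lam * raw_score - math.log(kp.K)) / math.log(2.0)
    evalue = kp.K * probe_length * subject_length * math.exp(-kp.lam * raw_score)
    return evalue, bit


# ---------------------------------------------------------------------------
# HSPs
# ---------------------------------------------------------------------------

@dataclass
class HSP:
    """A gapped local alignment of a protein probe to one translated frame.

    Intervals are 0-based half-open: query in aa, subject in forward-strand
    nucleotides.  ``subject_aln`` is the aligned subject translation with
    ``*`` marking stop codons.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    frame: int
    score: float
    bit_score: float
    evalue: float
    identity_pct: float
    query_aln: str
    subject_aln: str
    probe_name: str = ""

    @property
    def strand(self) -> int:
        return 1 if self.frame > 0 else -1

    def stop_positions(self) -> list[int]:
        """Forward-strand coordinates (leftmost nt) of aligned stop codons."""
        out = []
        aa_off = 0
        for qc, sc in zip(self.query_aln, self.subject_aln):
            if sc == "-":
                continue
            if sc == "*":
                if self.frame > 0:
                    out.append(self.subject_start + 3 * aa_off)
                else:
                    out.append(self.subject_end - 3 * (aa_off + 1))
            aa_off += 1
        return sorted(out)


@dataclass
class HitGroup:
    """Chained collinear HSPs of one probe on one subject.

    ``best_evalue`` is the best single-HSP E-value; ``chained_evalue`` (when
    statistics are available) converts the summed member scores, charged a
    junction penalty per chained break, through the same Karlin-Altschul
    formula — a deliberately simple group significance for elements whose
    reading frames are shattered by frameshifts.
    """

    probe_name: str
    hsps: list[HSP]
    query_cover_pct: float
    best_evalue: float
    chained_score: float | None = None
    chained_evalue: float | None = None

    @property
    def significance(self) -> float:
        """Best available E-value: single-HSP or chained, whichever is smaller."""
        if self.chained_evalue is None:
            return self.best_evalue
        return min(self.best_evalue, self.chained_evalue)

    @property
    def subject_start(self) -> int:
        return min(h.subject_start for h in self.hsps)

    @property
    def subject_end(self) -> int:
        return max(h.subject_end for h in self.hsps)

    @property
    def strand(self) -> int:
        return self.hsps[0].strand


@dataclass
class InactivationAnnotation:
    """Premature stops and frameshifts inferred from one hit group."""

    stop_positions: list[int]
    frameshift_positions: list[int]


# ---------------------------------------------------------------------------
# Smith-Waterman (row-vectorised affine gaps)
# ---------------------------------------------------------------------------

def _sw_score_matrix(qcodes: np.ndarray, scodes: np.ndarray, matrix: ScoringMatrix):
    """Fill the affine-gap local-alignment score matrix H (only H is stored).

    The within-row dependency of E is resolved with a running maximum over
    H0[k] + k*extend, which is exact because a horizontal gap run always
    originates at a cell whose value does not itself end in a horizontal gap.
    E and F values are recomputed on demand during traceback from their
    unrolled definitions.
    """
    m, n = len(qcodes), len(scodes)
    o = np.float32(matrix.gap_open)
    e = np.float32(matrix.gap_extend)
    oe = o + e
    # all scores and penalties are integers, so float32 arithmetic is exact
    H = np.zeros((m + 1, n + 1), dtype=np.float32)
    idx_e = np.arange(1, n + 1, dtype=np.float32) * e
    smat = matrix.scores.astype(np.float32)
    srows = smat[qcodes]                      # (m, 24)
    Fi = np.full(n, -1e18, dtype=np.float32)
    D = np.empty(n, dtype=np.float32)
    A = np.empty(n, dtype=np.float32)
    tmp = np.empty(n, dtype=np.float32)
    for i in range(1, m + 1):
        np.take(srows[i - 1], scodes, out=D)
        D += H[i - 1, :-1]
        np.subtract(H[i - 1, 1:], oe, out=tmp)
        Fi -= e
        np.maximum(tmp, Fi, out=Fi)
        np.maximum(D, Fi, out=D)
        np.maximum(D, np.float32(0.0), out=D)      # D is now H0
        np.add(D, idx_e, out=A)
        np.maximum.accumulate(A, out=A)
        row = H[i, 1:]
        np.maximum(A[:-1], np.float32(0.0), out=tmp[1:])
        tmp[0] = 0.0
        np.subtract(tmp, o, out=tmp)
        tmp -= idx_e
        np.maximum(D, tmp, out=row)
    return H


def _E_val(H, i, j, matrix):
    """E[i,j] = best score ending at (i,j) with a gap in the query."""
    if j < 1:
        return -1e18
    k = np.arange(j)
    return float(np.max(H[i, k] - matrix.gap_open - (j - k) * matrix.gap_extend))


def _F_val(H, i, j, matrix):
    """F[i,j] = best score ending at (i,j) with a gap in the subject."""
    if i < 1:
        return -1e18
    k = np.arange(i)
    return float(np.max(H[k, j] - matrix.gap_open - (i - k) * matrix.gap_extend))


def _traceback(H, qcodes, scodes, matrix, i, j, forbidden=()):
    """Recover one optimal path ending at (i, j); ties prefer diagonal,
    then gap-in-subject (up), then gap-in-query (left).  The walk aborts
    (returning None coordinates) as soon as it enters a forbidden subject
    interval — used to drop secondary endpoints that merge into an already
    reported alignment."""
    e = matrix.gap_extend
    q_aln: list[int] = []
    s_aln: list[int] = []
    state = "M"
    end_i, end_j = i, j
    while i > 0 and j > 0:
        if any(a < j <= b for a, b in forbidden):
            return None, None, end_i, end_j, [], []
        if state == "M":
            if H[i, j] <= 0:
                break
            diag = H[i - 1, j - 1] + matrix.scores[qcodes[i - 1], scodes[j - 1]]
            if H[i, j] == diag:
                q_aln.append(qcodes[i - 1])
                s_aln.append(scodes[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == _F_val(H, i, j, matrix):
                state = "F"
            elif H[i, j] == _E_val(H, i, j, matrix):
                state = "E"
            else:
                break
        elif state == "F":
            q_aln.append(qcodes[i - 1])
            s_aln.append(-1)
            if _F_val(H, i, j, matrix) == _F_val(H, i - 1, j, matrix) - e:
                i -= 1
            else:
                i -= 1
                state = "M"
        else:  # E
            q_aln.append(-1)
            s_aln.append(scodes[j - 1])
            if _E_val(H, i, j, matrix) == _E_val(H, i, j - 1, matrix) - e:
                j -= 1
            else:
                j -= 1
                state = "M"
    return i, j, end_i, end_j, q_aln[::-1], s_aln[::-1]


def _decode(codes: list[int]) -> str:
    return "".join("-" if c < 0 else AA_ALPHABET[c] for c in codes)


def _merge_windows(raw: list[tuple[int, int]], n: int) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in sorted((max(0, a), min(n, b)) for a, b in raw):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(hi, out[-1][1]))
        elif hi > lo:
            out.append((lo, hi))
    return out


def _find_windows(qcodes, fcodes, matrix, params: SearchParams):
    """Seed-derived windows (aa intervals on the frame) worth aligning.

    Small subjects (or ``seed_threshold <= 1``) use the sensitive mode: every
    positive seed word opens a window padded by the probe length, which makes
    the search provably exhaustive above the guaranteed score floor.  Larger
    subjects use banded clustering: seeds are grouped by diagonal bucket and
    subject position, and only clusters with ``min_cluster_seeds`` members
    open an alignment window — the standard sensitivity/speed trade of word
    seeding.
    """
    m, n = len(qcodes), len(fcodes)
    if m < params.word_size or n < params.word_size:
        return []
    if params.exhaustive:
        return [(0, n)]
    sensitive = params.seed_threshold <= 1.0 or n <= 2 * m + 50
    pair = matrix.scores[qcodes]                     # (m, 24)
    w2 = pair[:-1, :, None] + pair[1:, None, :]      # (m-1, 24, 24)
    wids = fcodes[:-1] * 24 + fcodes[1:]

    if sensitive:
        word_ok = (w2 >= params.seed_threshold).any(axis=0).ravel()
        js = np.nonzero(word_ok[wids])[0]
        if js.size == 0:
            return []
        pad = params.window_pad if params.window_pad is not None else m + 20
        gaps = np.diff(js)
        breaks = np.nonzero(gaps > params.window_join)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [js.size - 1]))
        return _merge_windows(
            [(int(js[s]) - pad, int(js[t]) + params.word_size + pad)
             for s, t in zip(starts, ends)], n)

    # fast mode: per-word query positions, then diagonal-band clustering
    hits = np.argwhere(w2 >= params.seed_threshold)   # (i, a, b)
    if hits.size == 0:
        return []
    word_of_hit = hits[:, 1] * 24 + hits[:, 2]
    order = np.argsort(word_of_hit, kind="stable")
    word_sorted = word_of_hit[order]
    qpos_sorted = hits[:, 0][order]
    word_start = np.searchsorted(word_sorted, np.arange(577))

    counts = word_start[wids + 1] - word_start[wids]
    keep = np.nonzero(counts)[0]
    if keep.size == 0:
        return []
    spos = np.repeat(keep, counts[keep])
    qpos = np.concatenate([
        qpos_sorted[word_start[w]: word_start[w + 1]] for w in wids[keep]])
    diag_bucket = (spos - qpos) // params.band_bucket

    pad2 = params.window_join + m // 4 + 10
    order2 = np.lexsort((spos, diag_bucket))
    db, sp = diag_bucket[order2], spos[order2]
    breaks = np.nonzero((np.diff(db) != 0) | (np.diff(sp) > params.window_join))[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(sp) - 1]))
    raw_windows = [
        (int(sp[s]) - pad2, int(sp[t]) + params.word_size + pad2)
        for s, t in zip(starts, ends)
        if t - s + 1 >= params.min_cluster_seeds
    ]
    return _merge_windows(raw_windows, n)


def _align_window(qcodes, fcodes, wlo, whi, matrix, params, out):
    """Extract subject-disjoint local alignments from one window.

    The score matrix is filled once; HSPs are taken greedily from the
    highest-scoring cells whose traceback does not overlap (on the subject)
    an alignment already reported — secondary endpoints that merge into an
    accepted path are rejected by that overlap test.
    """
    sub = fcodes[wlo:whi]
    if len(sub) < params.word_size or len(out) >= params.max_hsps_per_frame:
        return
    H = _sw_score_matrix(qcodes, sub, matrix)
    if float(H.max()) < params.min_raw_score:
        return
    # candidate endpoints: cells not profitably extensible on the diagonal
    terminal = np.ones_like(H, dtype=bool)
    terminal[:-1, :-1] = H[:-1, :-1] >= H[1:, 1:]
    ci, cj = np.nonzero((H >= params.min_raw_score) & terminal)
    vals = H[ci, cj]
    order = np.argsort(-vals, kind="stable")[:5000]
    used: list[tuple[int, int]] = []
    attempts = 0
    for k in order:
        if len(out) >= params.max_hsps_per_frame or attempts > 60:
            break
        i, j = int(ci[k]), int(cj[k])
        if any(a < j <= b for a, b in used):
            continue
        attempts += 1
        si, sj, ei, ej, q_aln, s_aln = _traceback(H, qcodes, sub, matrix, i, j,
                                                  forbidden=used)
        if si is None or sj == ej or any(not (ej <= a or sj >= b) for a, b in used):
            continue
        used.append((sj, ej))
        out.append((float(vals[k]), si, ei, wlo + sj, wlo + ej, q_aln, s_aln))


def local_align_translated(
    probe: str,
    subject: str,
    matrix: ScoringMatrix | None = None,
    params: SearchParams | None = None,
    probe_name: str = "",
) -> list[HSP]:
    """Search a protein probe against all six frames of a nucleotide subject.

    Returns HSPs above the score/E-value thresholds, best raw score first.
    Empty probe or subject yields an empty list.
    """
    matrix = matrix or ScoringMatrix.blosum45()
    params = params or SearchParams()
    if not probe or len(subject) < 3:
        return []
    if len(probe) < params.word_size and not params.exhaustive:
        raise ValueError("probe shorter than the seeding word size")

    qcodes = _AA_INDEX[np.frombuffer(probe.upper().encode(), np.uint8)]
    kp = cached_karlin_params(matrix, params)

    hsps: list[HSP] = []
    for frame in six_frame_translate(subject):
        if not frame.aa:
            continue
        fcodes = _AA_INDEX[np.frombuffer(frame.aa.encode(), np.uint8)]
        found: list = []
        for wlo, whi in _find_windows(qcodes, fcodes, matrix, params):
            _align_window(qcodes, fcodes, wlo, whi, matrix, params, found)
        for score, qs, qe, ss_aa, se_aa, q_aln, s_aln in found:
            evalue, bit = estimate_evalue(score, len(probe), len(subject), kp)
            if params.evalue_max is not None and evalue > params.evalue_max:
                continue
            nt_lo, nt_hi = frame.to_forward(ss_aa, se_aa)
            pairs = [(a, b) for a, b in zip(q_aln, s_aln) if a >= 0 and b >= 0]
            ident = sum(1 for a, b in pairs if a == b)
            hsps.append(HSP(
                query_start=qs, query_end=qe,
                subject_start=nt_lo, subject_end=nt_hi,
                frame=frame.frame, score=score, bit_score=bit, evalue=evalue,
                identity_pct=100.0 * ident / max(len(q_aln), 1),
                query_aln=_decode(q_aln), subject_aln=_decode(s_aln),
                probe_name=probe_name,
            ))
    hsps.sort(key=lambda h: (-h.score, h.subject_start))
    return hsps


# ---------------------------------------------------------------------------
# Chaining and annotation
# ---------------------------------------------------------------------------

def merge_hits(hsps: list[HSP], probe_length: int, max_gap: int = 900,
               query_slack: int = 15, kp: KarlinParams | None = None,
               subject_length: int | None = None,
               junction_penalty: float = 20.0) -> list[HitGroup]:
    """Chain collinear HSPs of one probe into hit groups.

    HSPs are chained when they lie on the same strand, their subject gap is
    at most ``max_gap`` nt, and their query order matches the subject order
    (within ``query_slack`` aa).  Opposite strands never chain.  Query cover
    is the union of query intervals as a percentage of the probe.
    """
    groups: list[HitGroup] = []
    for strand in (1, -1):
        pool = sorted((h for h in hsps if h.strand == strand),
                      key=lambda h: (h.subject_start, h.query_start))
        while pool:
            chain = _best_chain(pool, max_gap, query_slack)
            groups.append(_make_group(chain, probe_length, kp, subject_length,
                                      junction_penalty))
            taken = {id(h) for h in chain}
            pool = [h for h in pool if id(h) not in taken]
    groups.sort(key=lambda g: g.significance)
    return groups


def _best_chain(pool: list[HSP], max_gap: int, slack: int,
                max_overlap: int = 9) -> list[HSP]:
    """Maximum-total-score collinear chain (strictly advancing in query and
    subject, small overlaps allowed) among subject-sorted HSPs of one strand."""
    strand = pool[0].strand
    n = len(pool)
    best = [h.score for h in pool]
    prev_idx = [-1] * n
    for j in range(n):
        for i in range(j):
            a, b = pool[i], pool[j]
            gap = b.subject_start - a.subject_end
            if gap > max_gap or gap < -max_overlap:
                continue
            if strand > 0:
                ok = b.query_start >= a.query_end - slack
            else:
                ok = b.query_end <= a.query_start + slack
            if ok and best[i] + b.score > best[j]:
                best[j] = best[i] + b.score
                prev_idx[j] = i
    k = int(np.argmax(best))
    chain = []
    while k != -1:
        chain.append(pool[k])
        k = prev_idx[k]
    return chain[::-1]


def _make_group(chain: list[HSP], probe_length: int,
                kp: KarlinParams | None = None,
                subject_length: int | None = None,
                junction_penalty: float = 20.0) -> HitGroup:
    intervals = sorted((h.query_start, h.query_end) for h in chain)
    covered = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    chained_score = chained_evalue = None
    if kp is not None and subject_length is not None and len(chain) > 1:
        chained_score = (sum(h.score for h in chain)
                         - junction_penalty * (len(chain) - 1))
        chained_evalue, _ = estimate_evalue(
            chained_score, probe_length, subject_length, kp)
    return HitGroup(
        probe_name=chain[0].probe_name,
        hsps=sorted(chain, key=lambda h: h.subject_start),
        query_cover_pct=100.0 * covered / probe_length,
        best_evalue=min(h.evalue for h in chain),
        chained_score=chained_score,
        chained_evalue=chained_evalue,
    )


def _backbone(hsps: list[HSP], max_gap: int, slack: int = 3) -> list[HSP]:
    """Highest-scoring collinear subset (strictly advancing in query and
    subject, allowing ``slack`` aa of overlap) of one group's HSPs."""
    order = sorted(hsps, key=lambda h: h.subject_start)
    return _best_chain(order, max_gap, slack)


def annotate_inactivation(group: HitGroup, max_gap: int = 900) -> InactivationAnnotation:
    """Report premature stops and frameshifts for one chained hit group.

    Evidence is read off the group's backbone — the highest-scoring
    collinear subset of its HSPs, which discards spurious fragments that
    re-cover already-aligned probe regions.  Stops are the forward-strand
    coordinates of ``*`` codons inside backbone HSPs; a frameshift is the
    junction (left HSP's right edge) between adjacent backbone HSPs whose
    frames differ.
    """
    spine = _backbone(group.hsps, max_gap)
    stops: list[int] = []
    for h in spine:
        stops.extend(h.stop_positions())
    shifts: list[int] = []
    for prev, nxt in zip(spine, spine[1:]):
        if prev.frame != nxt.frame:
            shifts.append(prev.subject_end)
    return InactivationAnnotation(sorted(set(stops)), shifts)


def search_probes(
    probes: dict[str, str],
    subject: str,
    matrix: ScoringMatrix | None = None,
    params: SearchParams | None = None,
) -> dict[str, list[HitGroup]]:
    """Run every probe against one subject and chain the results."""
    matrix = matrix or ScoringMatrix.blosum45()
    params = params or SearchParams()
    kp = cached_karlin_params(matrix, params)
    out: dict[str, list[HitGroup]] = {}
    for name, probe in probes.items():
        hsps = local_align_translated(probe, subject, matrix, params, probe_name=name)
        out[name] = merge_hits(hsps, len(probe), kp=kp, subject_length=len(subject),
                               junction_penalty=params.chain_junction_penalty) if hsps else []
    return out


def cached_karlin_params(matrix: ScoringMatrix, params: SearchParams) -> KarlinParams:
    """Karlin-Altschul parameters, memoised on the matrix instance."""
    key = (params.background_freqs, params.gapped_scale if params.use_gapped_stats else None)
    cache = getattr(matrix, "_kp_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(matrix, "_kp_cache", cache)
    if key not in cache:
        cache[key] = karlin_params(matrix, params.background_freqs,
                                   gapped_scale=key[1])
    return cache[key]
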