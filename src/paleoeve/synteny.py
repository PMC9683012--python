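"""Synteny-anchored orthology and EVE presence calling.

Orthologous regions are located by translated search for the flanking
protein-coding landmark genes (three upstream, three downstream); the region
between the innermost located landmarks is then screened with the viral core
proteins.  Presence requires a core-protein hit below the E-value threshold
inside the region; absence is only called when the region itself is anchored
(both innermost landmarks found), so assembly gaps surface as 'ambiguous'
rather than as spurious losses.  An independent alignment-based method calls
presence from row coverage in a whole-genome-alignment slice, mirroring the
two-method cross-check of the screen.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alnkit import MultipleAlignment
from .seqsearch import HitGroup, ScoringMatrix, SearchParams, search_probes
from .synthsim import EveTemplate

PRESENT, ABSENT, AMBIGUOUS = "present", "absent", "ambiguous"

#: default translated-search E-value threshold for calling presence
PRESENCE_EVALUE = 1e-5
#: default extension when only one flank is anchored: the ancestral polymerase
#: length in amino acids
EXPECTED_ELEMENT_AA = 1053


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered landmark proteins flanking the integration locus."""

    upstream: tuple[str, ...]
    downstream: tuple[str, ...]
    proteins: dict[str, str]

    def __post_init__(self):
        if not self.upstream or not self.downstream:
            raise ValueError("need at least one landmark per side")
        names = list(self.upstream) + list(self.downstream)
        if len(set(names)) != len(names):
            raise ValueError("landmark names must be unique")
        missing = [n for n in names if not self.proteins.get(n)]
        if missing:
            raise ValueError(f"missing landmark protein sequences: {missing}")

    @property
    def ordered_names(self) -> tuple[str, ...]:
        return tuple(self.upstream) + tuple(self.downstream)


@dataclass
class LandmarkLocation:
    name: str
    start: int
    end: int
    strand: int
    evalue: float


@dataclass
class OrthoRegion:
    """Interval between the innermost located landmarks of one taxon."""

    taxon: str
    interval: tuple[int, int] | None
    located: dict[str, LandmarkLocation]
    rearranged: bool
    anchored_sides: int          # 0, 1 or 2

    @property
    def is_ambiguous(self) -> bool:
        return self.interval is None


@dataclass
class PresenceCall:
    taxon: str
    locus: str
    state: str
    method: str = "hit"
    hit_groups: list[HitGroup] = field(default_factory=list)
    arrangement_consistent: bool | None = None
    region: OrthoRegion | None = None

    def __post_init__(self):
        if self.state not in (PRESENT, ABSENT, AMBIGUOUS):
            raise ValueError(f"unknown presence state {self.state!r}")


# ---------------------------------------------------------------------------
# Landmark location and region definition
# ---------------------------------------------------------------------------

def locate_landmarks(
    taxon: str,
    sequence: str,
    landmarks: LandmarkSet,
    matrix: ScoringMatrix | None = None,
    params: SearchParams | None = None,
    evalue_max: float = 1e-3,
) -> OrthoRegion:
    """Find each landmark's best hit; absence of a landmark is data, not error."""
    params = params or SearchParams(evalue_max=evalue_max)
    located: dict[str, LandmarkLocation] = {}
    if sequence:
        results = search_probes(landmarks.proteins, sequence, matrix, params)
        for name, groups in results.items():
            best = next((g for g in groups if g.best_evalue <= evalue_max), None)
            if best is not None:
                located[name] = LandmarkLocation(
                    name, best.subject_start, best.subject_end,
                    best.strand, best.best_evalue)

    order = [located[n].start for n in landmarks.ordered_names if n in located]
    rearranged = any(b < a for a, b in zip(order, order[1:]))
    up = [located[n] for n in landmarks.upstream if n in located]
    dn = [located[n] for n in landmarks.downstream if n in located]
    anchored = int(bool(up)) + int(bool(dn))
    interval = None
    if up and dn and not rearranged:
        inner_up = max(loc.end for loc in up)
        inner_dn = min(loc.start for loc in dn)
        interval = (inner_up, max(inner_up, inner_dn))
    return OrthoRegion(taxon, interval, located, rearranged, anchored)


def define_ortho_region(
    region: OrthoRegion,
    sequence_length: int,
    expected_element_aa: int = EXPECTED_ELEMENT_AA,
) -> OrthoRegion:
    """Extend a one-side-anchored region by the expected element length.

    With both flanks anchored the interval is already the span between the
    innermost landmarks; with a single anchored side the region extends
    ``3 * expected_element_aa`` nucleotides into the unanchored direction.
    With neither side anchored the region stays ambiguous.
    """
    if region.interval is not None or region.anchored_sides == 0 or region.rearranged:
        return region
    ext = 3 * expected_element_aa
    ups = [loc for loc in region.located.values() if loc.name.startswith("UP")]
    if ups:
        anchor = max(loc.end for loc in ups)
        interval = (anchor, min(sequence_length, anchor + ext))
    else:
        anchor = min(loc.start for loc in region.located.values())
        interval = (max(0, anchor - ext), anchor)
    if interval[0] >= interval[1]:
        return region
    return OrthoRegion(region.taxon, interval, region.located,
                       region.rearranged, region.anchored_sides)


# ---------------------------------------------------------------------------
# Presence calling
# ---------------------------------------------------------------------------

def call_presence(
    taxon: str,
    sequence: str,
    region: OrthoRegion,
    core_probes: dict[str, str],
    locus: str = "locus",
    threshold: float = PRESENCE_EVALUE,
    min_probes: int = 1,
    matrix: ScoringMatrix | None = None,
    params: SearchParams | None = None,
    template: EveTemplate | None = None,
) -> PresenceCall:
    """Screen the orthologous region with the core proteins.

    Present requires at least ``min_probes`` core proteins with a hit group
    below ``threshold`` inside the region; an undefined region yields
    'ambiguous', never 'absent'.
    """
    if region.is_ambiguous:
        return PresenceCall(taxon, locus, AMBIGUOUS, region=region)
    lo, hi = region.interval
    if hi - lo < 3:
        return PresenceCall(taxon, locus, ABSENT, region=region)
    # exhaustive per-frame alignment inside the (small) region: degraded
    # elements survive as many weak fragments whose chained significance is
    # the evidence, so single-HSP E-value prefiltering is disabled here
    params = params or SearchParams(exhaustive=True, evalue_max=None)
    sub = sequence[lo:hi]
    results = search_probes(core_probes, sub, matrix, params)
    supporting: list[HitGroup] = []
    probes_hit = 0
    for name, groups in results.items():
        good = [g for g in groups if g.significance < threshold]
        if good:
            probes_hit += 1
            supporting.extend(good)
    if probes_hit >= min_probes:
        supporting = _shift_groups(supporting, lo)
        flag = check_arrangement(supporting, template) if template else None
        return PresenceCall(taxon, locus, PRESENT, hit_groups=supporting,
                            arrangement_consistent=flag, region=region)
    return PresenceCall(taxon, locus, ABSENT, region=region)


def _shift_groups(groups: list[HitGroup], offset: int) -> list[HitGroup]:
    for g in groups:
        for h in g.hsps:
            h.subject_start += offset
            h.subject_end += offset
    return groups


def check_arrangement(groups: list[HitGroup], template: EveTemplate | None = None) -> bool:
    """Hit order along the subject must match the canonical gene order.

    Missing genes are allowed; the order may read forward or reverse
    (element orientation is arbitrary), but the integrase and major capsid
    must lie on the same strand when both are detected.
    """
    template = template or EveTemplate()
    order = {g.name: i for i, g in enumerate(template.genes)}
    best: dict[str, HitGroup] = {}
    for g in groups:
        if g.probe_name in order:
            cur = best.get(g.probe_name)
            if cur is None or g.best_evalue < cur.best_evalue:
                best[g.probe_name] = g
    if len(best) < 2:
        return True
    ranked = sorted(best.values(), key=lambda g: g.subject_start)
    idx = [order[g.probe_name] for g in ranked]
    monotone = idx == sorted(idx) or idx == sorted(idx, reverse=True)
    strands_ok = True
    if "INT" in best and "MCP" in best:
        strands_ok = best["INT"].strand == best["MCP"].strand
    return monotone and strands_ok


def screen_taxon(
    taxon: str,
    sequence: str,
    landmarks: LandmarkSet,
    core_probes: dict[str, str],
    locus: str = "locus",
    threshold: float = PRESENCE_EVALUE,
    template: EveTemplate | None = None,
    matrix: ScoringMatrix | None = None,
    expected_element_aa: int = EXPECTED_ELEMENT_AA,
) -> PresenceCall:
    """Locate landmarks, define the orthologous region, and call presence."""
    region = locate_landmarks(taxon, sequence, landmarks, matrix)
    region = define_ortho_region(region, len(sequence), expected_element_aa)
    return call_presence(taxon, sequence, region, core_probes, locus=locus,
                         threshold=threshold, matrix=matrix, template=template)


# ---------------------------------------------------------------------------
# Alignment-based presence (whole-genome-alignment slice)
# ---------------------------------------------------------------------------

def presence_from_alignment(
    aln: MultipleAlignment,
    eve_columns: tuple[int, int],
    locus: str = "locus",
    min_coverage: float = 0.3,
) -> list[PresenceCall]:
    """Presence from row coverage of the EVE columns of an alignment slice.

    A taxon is present when at least ``min_coverage`` of the EVE columns are
    non-gap; absent when the EVE columns are empty but the rest of the slice
    is covered; ambiguous when the taxon is essentially missing from the
    slice altogether.
    """
    lo, hi = eve_columns
    arr = aln.to_array()
    gap = ord("-")
    calls = []
    flank_mask = np.ones(aln.n_columns, dtype=bool)
    flank_mask[lo:hi] = False
    for i, taxon in enumerate(aln.ids):
        inside = (arr[i, lo:hi] != gap).mean() if hi > lo else 0.0
        outside = (arr[i, flank_mask] != gap).mean() if flank_mask.any() else 0.0
        if inside >= min_coverage:
            state = PRESENT
        elif outside >= min_coverage:
            state = ABSENT
        else:
            state = AMBIGUOUS
        calls.append(PresenceCall(taxon, locus, state, method="alignment"))
    return calls


# ---------------------------------------------------------------------------
# Presence matrix and method comparison
# ---------------------------------------------------------------------------

class PresenceMatrix:
    """Taxa x loci grid of presence calls, keyed also by method."""

    def __init__(self):
        self._calls: dict[tuple[str, str, str], PresenceCall] = {}

    def add(self, call: PresenceCall) -> None:
        key = (call.taxon, call.locus, call.method)
        if key in self._calls:
            raise ValueError(f"duplicate call for {key}")
        self._calls[key] = call

    @property
    def taxa(self) -> list[str]:
        return sorted({t for t, _, _ in self._calls})

    @property
    def loci(self) -> list[str]:
        return sorted({l for _, l, _ in self._calls})

    @property
    def methods(self) -> list[str]:
        return sorted({m for _, _, m in self._calls})

    def state(self, taxon: str, locus: str, method: str = "hit") -> str | None:
        call = self._calls.get((taxon, locus, method))
        return call.state if call else None

    def call(self, taxon: str, locus: str, method: str = "hit") -> PresenceCall | None:
        return self._calls.get((taxon, locus, method))

    def presence_dict(self, locus: str, method: str = "hit") -> dict[str, str]:
        return {t: c.state for (t, l, m), c in self._calls.items()
                if l == locus and m == method}

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"taxon": t, "locus": l, "method": m, "state": c.state,
             "arrangement_consistent": c.arrangement_consistent}
            for (t, l, m), c in sorted(self._calls.items())
        ]
        return pd.DataFrame(rows)


def build_presence_matrix(calls: list[PresenceCall]) -> PresenceMatrix:
    if not calls:
        raise ValueError("need at least one presence call")
    matrix = PresenceMatrix()
    for call in calls:
        matrix.add(call)
    return matrix


@dataclass
class MethodComparison:
    shared: list[tuple[str, str]]
    discordant: list[tuple[str, str, str, str]]   # taxon, locus, state_a, state_b

    @property
    def agreement(self) -> float:
        if not self.shared:
            return float("nan")
        return 1.0 - len(self.discordant) / len(self.shared)


def compare_methods(matrix: PresenceMatrix, method_a: str = "hit",
                    method_b: str = "alignment") -> MethodComparison:
    """List taxon-locus cells where two methods disagree (never reconciled)."""
    shared, discordant = [], []
    for taxon in matrix.taxa:
        for locus in matrix.loci:
            sa = matrix.state(taxon, locus, method_a)
            sb = matrix.state(taxon, locus, method_b)
            if sa is None or sb is None:
                continue
            shared.append((taxon, locus))
            if sa != sb:
                discordant.append((taxon, locus, sa, sb))
    return MethodComparison(shared, discordant)
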