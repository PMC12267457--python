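"""Taxonomic identification from picked peaks.

Each panel marker is matched against the peaks falling in its nominal m/z
window; for every replicate the candidate taxon set is the intersection,
over matched markers, of the leaves consistent with the observed mass
(absent markers impose no constraint).  The reported identification is the
smallest named category covering the candidates.  A sample is *identified*
only when at least ``min_markers`` distinct markers matched (four by
default) and the candidate set is nonempty; an empty intersection with
enough markers is a flagged conflict, not a root-level identification.

Triplicate MALDI spots are resolved individually and then combined: under
the default union-consistent rule, replicates whose candidate sets are
nested (or grouped by a common named category) pool their marker matches
and are re-resolved; disjoint replicates are a conflict and fall back to a
strict intersection of their evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .marker_reference import ReferenceLibrary, minimal_category
from .preprocessing import PreprocessConfig, preprocess
from .spectral_io import PeakList, Spectrum

__all__ = [
    "MatchConfig",
    "MarkerMatch",
    "Identification",
    "match_markers",
    "resolve_taxon",
    "combine_replicates",
    "classify_sample",
]


@dataclass(frozen=True)
class MatchConfig:
    """Matching and success-criterion parameters.

    ``mz_tolerance`` (0.5 Da default) separates the library's diagnostic
    contrasts while absorbing centroiding and calibration error;
    ``min_markers`` is the >= 4-marker success criterion applied to the
    combined, post-consensus marker count.
    """

    mz_tolerance: float = 0.5
    min_markers: int = 4
    max_markers: int = 9
    consensus_rule: str = "union-consistent"

    def __post_init__(self):
        if not 0 < self.mz_tolerance <= 2:
            raise ValueError("mz_tolerance must be in (0, 2] Da")
        if not 1 <= self.min_markers <= self.max_markers:
            raise ValueError("need 1 <= min_markers <= max_markers")
        if self.consensus_rule not in ("union-consistent", "strict-intersection"):
            raise ValueError(f"unknown consensus_rule {self.consensus_rule!r}")


@dataclass(frozen=True)
class MarkerMatch:
    """Best peak-to-marker assignment for one panel marker.

    ``matched_values`` lists every expected value within tolerance of the
    chosen peak together with the leaves carrying it; ``leaves`` is their
    union (the taxa consistent with this observation).
    """

    marker_id: str
    observed_mz: float
    matched_values: tuple[tuple[float, frozenset[str]], ...]
    best_delta: float

    @property
    def leaves(self) -> frozenset[str]:
        out: set[str] = set()
        for _, taxa in self.matched_values:
            out |= taxa
        return frozenset(out)


@dataclass(frozen=True)
class Identification:
    """Per-sample (or per-replicate) category call."""

    sample_id: str
    status: str  # "identified" | "fail"
    category: str | None
    n_markers: int
    replicate_agreement: str  # "full" | "partial" | "single" | "conflict"
    matches: tuple[MarkerMatch, ...] = ()
    candidates: frozenset[str] = field(default_factory=frozenset)
    conflict: bool = False

    @property
    def identified(self) -> bool:
        return self.status == "identified"


def match_markers(
    peaks: PeakList, lib: ReferenceLibrary, cfg: MatchConfig = MatchConfig()
) -> list[MarkerMatch]:
    """At most one MarkerMatch per panel marker.

    Among the in-window peaks with at least one expected value within
    ±mz_tolerance, the peak with the smallest |delta| wins (ties broken by
    higher intensity); all in-tolerance expected values of that peak are
    carried, so a peak equidistant from two variant groups keeps both.
    """
    matches = []
    for marker in lib.panel:
        lo, hi = marker.window
        best = None  # (abs_delta, -intensity, MarkerMatch)
        for peak in peaks.peaks:
            if not lo <= peak.mz <= hi:
                continue
            by_value: dict[float, set[str]] = {}
            for leaf in lib.leaves.values():
                for v in leaf.marker_mz.get(marker.marker_id, ()):
                    if abs(v - peak.mz) <= cfg.mz_tolerance:
                        by_value.setdefault(v, set()).add(leaf.name)
            if not by_value:
                continue
            delta = min((v - peak.mz for v in by_value), key=abs)
            match = MarkerMatch(
                marker_id=marker.marker_id,
                observed_mz=peak.mz,
                matched_values=tuple(
                    (v, frozenset(by_value[v])) for v in sorted(by_value)
                ),
                best_delta=delta,
            )
            key = (abs(delta), -peak.intensity)
            if best is None or key < best[0]:
                best = (key, match)
        if best is not None:
            matches.append(best[1])
    return matches


def resolve_taxon(
    matches: list[MarkerMatch],
    lib: ReferenceLibrary,
    cfg: MatchConfig = MatchConfig(),
    sample_id: str = "",
    replicate_agreement: str = "single",
) -> Identification:
    """Intersect per-marker candidate sets and name the minimal category."""
    candidates = frozenset(lib.leaves)
    for m in matches:
        candidates &= m.leaves
    n_markers = len({m.marker_id for m in matches})
    conflict = bool(matches) and not candidates
    if n_markers >= cfg.min_markers and candidates:
        status, category = "identified", minimal_category(lib, candidates)
    else:
        status, category = "fail", None
    return Identification(
        sample_id=sample_id,
        status=status,
        category=category,
        n_markers=n_markers,
        replicate_agreement=replicate_agreement,
        matches=tuple(matches),
        candidates=candidates if matches else frozenset(),
        conflict=conflict,
    )


def _consistent(a: Identification, b: Identification, lib: ReferenceLibrary) -> bool:
    """Replicates agree when one candidate set contains the other, or a
    (non-root) named category groups both."""
    ca = a.candidates if a.matches else frozenset(lib.leaves)
    cb = b.candidates if b.matches else frozenset(lib.leaves)
    if not ca or not cb:
        return False
    if ca <= cb or cb <= ca:
        return True
    union = ca | cb
    all_leaves = frozenset(lib.leaves)
    return any(
        union <= c.members for c in lib.categories.values() if c.members != all_leaves
    )


def combine_replicates(
    ids: list[Identification],
    lib: ReferenceLibrary,
    cfg: MatchConfig = MatchConfig(),
) -> Identification:
    """Combine 1-3 replicate identifications of one sample."""
    if not ids:
        raise ValueError("no replicate identifications given")
    sample_ids = {i.sample_id for i in ids}
    if len(sample_ids) > 1:
        raise ValueError(f"replicates from different samples: {sorted(sample_ids)}")
    sample_id = ids[0].sample_id

    if len(ids) == 1:
        return replace(ids[0], replicate_agreement="single")

    informative = [i for i in ids if i.matches]
    pairs_ok = all(
        _consistent(a, b, lib)
        for k, a in enumerate(informative)
        for b in informative[k + 1 :]
    )
    use_union = cfg.consensus_rule == "union-consistent" and pairs_ok

    if use_union:
        merged = _merge_matches([m for i in ids for m in i.matches], cfg)
        if len({(i.candidates, i.n_markers) for i in informative}) <= 1 and len(
            informative
        ) == len(ids):
            agreement = "full"
        else:
            agreement = "partial"
        return resolve_taxon(
            merged, lib, cfg, sample_id=sample_id, replicate_agreement=agreement
        )

    # conflict (or strict-intersection requested): keep only markers matched
    # in every informative replicate and intersect their leaf sets
    agreement = "conflict" if not pairs_ok else "partial"
    if not informative:
        return resolve_taxon([], lib, cfg, sample_id=sample_id, replicate_agreement=agreement)
    common = set.intersection(*({m.marker_id for m in i.matches} for i in informative))
    merged = []
    for mid in sorted(common):
        per_rep = [next(m for m in i.matches if m.marker_id == mid) for i in informative]
        leaves = frozenset.intersection(*(m.leaves for m in per_rep))
        first = per_rep[0]
        merged.append(
            MarkerMatch(
                marker_id=mid,
                observed_mz=first.observed_mz,
                matched_values=((first.observed_mz + first.best_delta, leaves),) if leaves else (),
                best_delta=first.best_delta,
            )
        )
    out = resolve_taxon(merged, lib, cfg, sample_id=sample_id, replicate_agreement=agreement)
    if agreement == "conflict":
        out = replace(out, conflict=True, status="fail" if not out.candidates else out.status)
    return out


def _merge_matches(matches: list[MarkerMatch], cfg: MatchConfig) -> list[MarkerMatch]:
    """One match per marker: smallest |delta| wins, values pooled."""
    by_marker: dict[str, list[MarkerMatch]] = {}
    for m in matches:
        by_marker.setdefault(m.marker_id, []).append(m)
    merged = []
    for mid, group in by_marker.items():
        group.sort(key=lambda m: abs(m.best_delta))
        values: dict[float, frozenset[str]] = {}
        for m in group:
            for v, taxa in m.matched_values:
                values[v] = values.get(v, frozenset()) | taxa
        best = group[0]
        merged.append(
            MarkerMatch(
                marker_id=mid,
                observed_mz=best.observed_mz,
                matched_values=tuple((v, values[v]) for v in sorted(values)),
                best_delta=best.best_delta,
            )
        )
    merged.sort(key=lambda m: m.marker_id)
    return merged


def classify_sample(
    spectra: list[Spectrum],
    lib: ReferenceLibrary,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    match_cfg: MatchConfig = MatchConfig(),
) -> Identification:
    """Full chain per replicate (baseline -> smooth -> pick -> match ->
    resolve), then replicate consensus.  Deterministic for fixed inputs."""
    if not spectra:
        raise ValueError("no spectra given")
    sample_ids = {s.sample_id for s in spectra}
    if len(sample_ids) > 1:
        raise ValueError(f"spectra from different samples: {sorted(sample_ids)}")
    per_replicate = []
    for s in spectra:
        peaks = preprocess(s, pre_cfg)
        matches = match_markers(peaks, lib, match_cfg)
        per_replicate.append(
            resolve_taxon(matches, lib, match_cfg, sample_id=s.sample_id)
        )
    return combine_replicates(per_replicate, lib, match_cfg)
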