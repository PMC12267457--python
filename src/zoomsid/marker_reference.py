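"""Collagen peptide-marker reference library and taxonomic-category lattice.

A ZooMS reference library holds, for each leaf taxon (genus or species group),
the expected singly-protonated monoisotopic masses of a panel of diagnostic
tryptic collagen peptides ("markers", labelled by chain and residue range,
e.g. ``COL1a2 757-789``, with a single panel letter code).  Identification
reports the smallest *named category* of taxa consistent with the observed
markers, so the library also carries a lattice of named categories (leaf
singletons, compound groups such as ``Cervid/Rupicapra``, and a root
containing every leaf).

Masses are treated throughout as [M+H]+ monoisotopic values in Da; no charge
states beyond +1 and no deamidation expansion (sub-Dalton shifts are absorbed
by the matching tolerance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PeptideMarker",
    "LeafTaxon",
    "TaxonCategory",
    "ReferenceLibrary",
    "LibraryValidationError",
    "LibraryFormatError",
    "load_library",
    "write_library",
    "default_library",
    "candidate_taxa",
    "minimal_category",
    "validate_library",
]

#: MALDI reflector mass range (Da) within which all marker windows must fall.
MZ_RANGE = (800.0, 3600.0)

#: Minimum m/z separation (Da) for two expected values to count as distinct
#: when checking that a marker distinguishes a pair of leaves.
SEPARATION_TOL = 0.5


class LibraryValidationError(ValueError):
    """Raised when a library violates its invariants; carries every violation."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid reference library:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class LibraryFormatError(ValueError):
    """Raised when a library file cannot be parsed."""


@dataclass(frozen=True)
class PeptideMarker:
    """One diagnostic collagen peptide of the panel.

    ``window`` is the nominal [min, max] m/z range (Da) within which every
    taxon's variants of this peptide fall; matching only considers peaks
    inside the window.
    """

    marker_id: str
    letter_code: str
    window: tuple[float, float]


@dataclass(frozen=True)
class LeafTaxon:
    """A terminal taxon with its expected marker masses.

    ``marker_mz`` maps marker_id -> tuple of expected [M+H]+ values (a marker
    may have more than one variant per taxon, e.g. differing hydroxylation).
    Markers missing from the mapping are uninformative for this taxon.
    ``provenance`` maps marker_id -> citation tag, ``"anchor"`` for values
    fixed from the site study's published contrasts, ``"literature"`` for
    values assembled from general ZooMS compilations.
    """

    name: str
    marker_mz: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self,
            "marker_mz",
            {k: tuple(float(v) for v in vals) for k, vals in dict(self.marker_mz).items()},
        )
        object.__setattr__(self, "provenance", dict(self.provenance))

    def __eq__(self, other):
        if not isinstance(other, LeafTaxon):
            return NotImplemented
        return (
            self.name == other.name
            and dict(self.marker_mz) == dict(other.marker_mz)
            and dict(self.provenance) == dict(other.provenance)
        )

    def __hash__(self):
        return hash((self.name, tuple(sorted(self.marker_mz.items()))))


@dataclass(frozen=True)
class TaxonCategory:
    """A named group of leaf taxa (node of the reporting lattice)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class ReferenceLibrary:
    """Marker panel + leaves + category lattice.

    The panel size *is* the declared maximum marker count for identification
    (nine in standard ZooMS practice).  Singleton categories for every leaf
    and a root category covering all leaves are added automatically when the
    library is built through :func:`load_library` / :func:`build_library`.
    """

    panel: tuple[PeptideMarker, ...]
    leaves: dict[str, LeafTaxon]
    categories: dict[str, TaxonCategory]

    @property
    def max_markers(self) -> int:
        return len(self.panel)

    @property
    def panel_ids(self) -> tuple[str, ...]:
        return tuple(m.marker_id for m in self.panel)

    def marker(self, marker_id: str) -> PeptideMarker:
        for m in self.panel:
            if m.marker_id == marker_id:
                return m
        raise KeyError(f"unknown marker_id: {marker_id!r}")

    @property
    def root(self) -> TaxonCategory:
        all_leaves = frozenset(self.leaves)
        for cat in sorted(self.categories.values(), key=lambda c: c.name):
            if cat.members == all_leaves:
                return cat
        raise LibraryValidationError(["no root category covering all leaves"])

    def __eq__(self, other):
        if not isinstance(other, ReferenceLibrary):
            return NotImplemented
        return (
            self.panel == other.panel
            and self.leaves == other.leaves
            and self.categories == other.categories
        )


# ---------------------------------------------------------------------------
# construction and validation


def build_library(
    panel: Iterable[PeptideMarker],
    leaves: Iterable[LeafTaxon],
    categories: Iterable[TaxonCategory] = (),
    root_name: str = "All taxa",
    validate: bool = True,
) -> ReferenceLibrary:
    """Assemble a library, adding implicit leaf singletons and a root.

    Raises :class:`LibraryValidationError` when ``validate`` and any
    invariant is violated.
    """
    panel = tuple(panel)
    leaf_map = {lf.name: lf for lf in leaves}
    cat_map = {c.name: c for c in categories}
    # implicit singleton category per leaf (a leaf's own reported name)
    for name in leaf_map:
        cat_map.setdefault(name, TaxonCategory(name, frozenset({name})))
    # implicit root unless some category already covers everything
    if not any(c.members == frozenset(leaf_map) for c in cat_map.values()):
        cat_map[root_name] = TaxonCategory(root_name, frozenset(leaf_map))
    lib = ReferenceLibrary(panel=panel, leaves=leaf_map, categories=cat_map)
    if validate:
        report = validate_library(lib)
        if report:
            raise LibraryValidationError(report)
    return lib


def _pair_distinguished(a: LeafTaxon, b: LeafTaxon, panel_ids: Sequence[str]) -> bool:
    for mid in panel_ids:
        va, vb = a.marker_mz.get(mid), b.marker_mz.get(mid)
        if not va or not vb:
            continue
        if all(abs(x - y) > SEPARATION_TOL for x in va for y in vb):
            return True
    return False


def validate_library(lib: ReferenceLibrary) -> list[str]:
    """Return a report listing every invariant violation (empty iff valid)."""
    report: list[str] = []
    lo, hi = MZ_RANGE

    letters = [m.letter_code for m in lib.panel]
    if len(set(letters)) != len(letters):
        dupes = sorted({c for c in letters if letters.count(c) > 1})
        report.append(f"duplicate letter codes in panel: {dupes}")
    ids = [m.marker_id for m in lib.panel]
    if len(set(ids)) != len(ids):
        report.append("duplicate marker_ids in panel")
    for m in lib.panel:
        wlo, whi = m.window
        if not (lo <= wlo < whi <= hi):
            report.append(
                f"marker {m.marker_id}: window {m.window} outside [{lo:g}, {hi:g}] Da"
            )

    panel_ids = set(lib.panel_ids)
    for leaf in lib.leaves.values():
        for mid, values in leaf.marker_mz.items():
            if mid not in panel_ids:
                report.append(f"leaf {leaf.name}: value for unknown marker {mid!r}")
                continue
            wlo, whi = lib.marker(mid).window
            for v in values:
                if not (wlo <= v <= whi):
                    report.append(
                        f"leaf {leaf.name}: {mid} m/z {v:g} outside window [{wlo:g}, {whi:g}]"
                    )

    all_leaves = frozenset(lib.leaves)
    for cat in lib.categories.values():
        if not cat.members:
            report.append(f"category {cat.name!r} is empty")
        unknown = cat.members - all_leaves
        if unknown:
            report.append(f"category {cat.name!r} references unknown leaves: {sorted(unknown)}")
    if not any(c.members == all_leaves for c in lib.categories.values()):
        report.append("no root category covering all leaves")

    # every leaf pair must be separable by some marker or grouped by a
    # non-root named category (the root would make this vacuous; in a
    # <= 2-leaf library the only possible grouping *is* the root, so the
    # restriction is waived there)
    if len(all_leaves) <= 2:
        non_root = list(lib.categories.values())
    else:
        non_root = [c for c in lib.categories.values() if c.members != all_leaves]
    names = sorted(lib.leaves)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if _pair_distinguished(lib.leaves[a], lib.leaves[b], lib.panel_ids):
                continue
            if any({a, b} <= c.members for c in non_root):
                continue
            report.append(
                f"leaves {a!r} and {b!r} share all markers but no named category groups them"
            )
    return report


# ---------------------------------------------------------------------------
# queries


def candidate_taxa(
    lib: ReferenceLibrary, marker_id: str, observed_mz: float, tol: float
) -> set[str]:
    """Leaves with an expected value for ``marker_id`` within ±``tol`` Da.

    The tolerance is inclusive.  An empty set means the observed mass matches
    no known taxon on this marker.
    """
    if tol <= 0:
        # tol=0 still permitted conceptually (exact match); negative is not
        if tol < 0:
            raise ValueError("tol must be >= 0")
    lib.marker(marker_id)  # raises KeyError for unknown markers
    out = set()
    for leaf in lib.leaves.values():
        for v in leaf.marker_mz.get(marker_id, ()):
            if abs(v - observed_mz) <= tol:
                out.add(leaf.name)
                break
    return out


def minimal_category(lib: ReferenceLibrary, taxa: Iterable[str]) -> str:
    """Name of the smallest named category whose members cover ``taxa``.

    Ties on member count break lexicographically by category name, so the
    result is deterministic.  The root is returned when no smaller category
    covers the set.  Raises ``ValueError`` on an empty set and ``KeyError``
    on taxa unknown to the library.
    """
    taxa = frozenset(taxa)
    if not taxa:
        raise ValueError("taxa set must be nonempty")
    unknown = taxa - frozenset(lib.leaves)
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    covering = [c for c in lib.categories.values() if taxa <= c.members]
    # the root always covers, so `covering` is nonempty for valid libraries
    best = min(covering, key=lambda c: (len(c.members), c.name))
    return best.name


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ["leaf", "marker_id", "letter_code", "mz", "provenance"]


def _library_to_doc(lib: ReferenceLibrary) -> dict:
    return {
        "panel": [
            {"marker_id": m.marker_id, "letter_code": m.letter_code, "window": list(m.window)}
            for m in lib.panel
        ],
        "leaves": [
            {
                "name": lf.name,
                "markers": {
                    mid: {"mz": list(vals), "provenance": lf.provenance.get(mid, "literature")}
                    for mid, vals in lf.marker_mz.items()
                },
            }
            for lf in lib.leaves.values()
        ],
        "categories": {c.name: sorted(c.members) for c in lib.categories.values()},
    }


def _library_from_doc(doc: dict) -> ReferenceLibrary:
    try:
        panel = [
            PeptideMarker(p["marker_id"], p["letter_code"], tuple(p["window"]))
            for p in doc["panel"]
        ]
        leaves = []
        for entry in doc["leaves"]:
            marker_mz = {mid: tuple(spec["mz"]) for mid, spec in entry["markers"].items()}
            prov = {mid: spec.get("provenance", "literature") for mid, spec in entry["markers"].items()}
            leaves.append(LeafTaxon(entry["name"], marker_mz, prov))
        categories = [
            TaxonCategory(name, frozenset(members))
            for name, members in doc.get("categories", {}).items()
        ]
    except (KeyError, TypeError) as exc:
        raise LibraryFormatError(f"malformed library document: missing/invalid field {exc}") from exc
    return build_library(panel, leaves, categories)


def load_library(path: str | Path, format: str | None = None) -> ReferenceLibrary:
    """Read and validate a reference library from JSON or TSV.

    JSON is a single document with ``panel`` / ``leaves`` / ``categories``
    keys.  TSV holds one row per (leaf, marker) with columns
    ``leaf, marker_id, letter_code, mz, provenance`` (several values for one
    marker separated by ``;`` in the mz column, or repeated rows) plus a
    sidecar ``<stem>.categories.json`` mapping category name -> members,
    with an optional ``_windows`` key for marker windows.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise LibraryFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        return _library_from_doc(doc)
    if fmt != "tsv":
        raise ValueError(f"unknown library format: {fmt!r}")

    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise LibraryFormatError(
                f"{path}: line 1: expected columns {_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise LibraryFormatError(f"{path}: line {lineno}: expected 5 fields")
            try:
                mzs = tuple(float(v) for v in fields[3].split(";"))
            except ValueError as exc:
                raise LibraryFormatError(f"{path}: line {lineno}: bad mz field {fields[3]!r}") from exc
            rows.append((fields[0], fields[1], fields[2], mzs, fields[4]))

    sidecar = path.with_suffix(path.suffix + ".categories.json") if path.suffix != ".tsv" else path.with_name(path.stem + ".categories.json")
    meta: dict = {}
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise LibraryFormatError(f"{sidecar}: invalid JSON: {exc.msg}") from exc
    windows = meta.pop("_windows", {})

    panel: dict[str, PeptideMarker] = {}
    leaf_values: dict[str, dict[str, tuple[float, ...]]] = {}
    leaf_prov: dict[str, dict[str, str]] = {}
    for leaf, mid, letter, mzs, prov in rows:
        if mid not in panel:
            win = windows.get(mid)
            if win is None:
                # infer a generous nominal window from the observed values
                vals = [v for r in rows if r[1] == mid for v in r[3]]
                win = [max(MZ_RANGE[0], min(vals) - 25.0), min(MZ_RANGE[1], max(vals) + 25.0)]
            panel[mid] = PeptideMarker(mid, letter, (float(win[0]), float(win[1])))
        prev = leaf_values.setdefault(leaf, {}).get(mid, ())
        leaf_values[leaf][mid] = prev + mzs
        leaf_prov.setdefault(leaf, {})[mid] = prov
    leaves = [LeafTaxon(n, leaf_values[n], leaf_prov[n]) for n in leaf_values]
    categories = [TaxonCategory(n, frozenset(m)) for n, m in meta.items()]
    return build_library(panel.values(), leaves, categories)


def write_library(lib: ReferenceLibrary, path: str | Path, format: str | None = None) -> Path:
    """Write a library to JSON, or to TSV plus its categories sidecar."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        path.write_text(json.dumps(_library_to_doc(lib), indent=1))
        return path
    if fmt != "tsv":
        raise ValueError(f"unknown library format: {fmt!r}")
    lines = ["\t".join(_TSV_COLUMNS)]
    letter = {m.marker_id: m.letter_code for m in lib.panel}
    for leaf in lib.leaves.values():
        for mid in lib.panel_ids:
            if mid in leaf.marker_mz:
                mzs = ";".join(f"{v:g}" for v in leaf.marker_mz[mid])
                lines.append(
                    "\t".join(
                        [leaf.name, mid, letter[mid], mzs, leaf.provenance.get(mid, "literature")]
                    )
                )
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_name(path.stem + ".categories.json")
    meta = {c.name: sorted(c.members) for c in lib.categories.values()}
    meta["_windows"] = {m.marker_id: list(m.window) for m in lib.panel}
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def default_library() -> ReferenceLibrary:
    """The packaged default library (9-marker panel, 24 leaf taxa).

    The three published site contrasts (cervid 3017/3033 vs roe deer
    3043/3059 on COL1a2 757-789; 1580 vs 1550 on COL1a2 502-519; canid
    1576.8 on COL1a2 889-906) are fixed ``"anchor"`` values; remaining
    masses are internally consistent stand-ins in the style of published
    ZooMS compilations (``"literature"``) and the library is replaceable.
    """
    ref = resources.files("zoomsid.data").joinpath("default_library.json")
    with resources.as_file(ref) as p:
        return load_library(p, format="json")
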