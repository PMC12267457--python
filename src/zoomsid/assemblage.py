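"""Assemblage-level quantification: ZNISP tables, broad-category mapping,
comparison with morphological NISP, and spatial success grids.

ZNISP ("ZooMS Number of Identified Specimens") tables count identifications
per reported category and stratum (stratigraphic layer or cultural complex).
Percentages follow the published convention: per-category share of the
stratum total *including* failed samples, rounded half-up to one decimal;
headline success rates are rounded half-up to integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .identification import Identification
from .spectral_io import SampleRecord

__all__ = [
    "FAIL",
    "ZNISPTable",
    "ComparisonTable",
    "SuccessGrid",
    "round_half_up",
    "tabulate_znisp",
    "success_rate",
    "map_broad",
    "compare_with_morph",
    "spatial_success",
    "plot_success_grid",
    "load_znisp_fixture",
    "load_morph_fixture",
    "load_broad_map",
    "expand_fixture",
]

FAIL = "Fail"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (1263 -> 88% style table arithmetic)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ZNISPTable:
    """Counts per category x stratum; the ``Fail`` row is carried separately.

    ``counts``: DataFrame indexed by category (no Fail row), one column per
    stratum.  ``fails``: Series of failed-sample counts per stratum.
    """

    counts: pd.DataFrame
    fails: pd.Series

    def __post_init__(self):
        self.counts = self.counts.fillna(0).astype(int)
        self.fails = self.fails.reindex(self.counts.columns).fillna(0).astype(int)
        bad = self.counts.lt(0).any().any() or self.fails.lt(0).any()
        if bad:
            raise ValueError("ZNISP counts must be nonnegative")

    @property
    def strata(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Per-stratum totals including fails."""
        return self.counts.sum() + self.fails

    def identified(self) -> pd.Series:
        return self.counts.sum()

    def percentages(self) -> pd.DataFrame:
        """Per-category percentage of the stratum total (fails included),
        with a Fail row, rounded half-up to one decimal."""
        full = pd.concat([self.counts, self.fails.to_frame(FAIL).T])
        totals = self.totals()
        pct = full.div(totals, axis=1) * 100.0
        return pct.map(lambda v: round_half_up(v, 1))

    def with_fail_row(self) -> pd.DataFrame:
        return pd.concat([self.counts, self.fails.to_frame(FAIL).T])


def tabulate_znisp(
    ids: list[Identification],
    records: list[SampleRecord],
    stratum: str = "complex",
) -> ZNISPTable:
    """Count identifications per category x stratum ("layer" or "complex")."""
    if stratum not in ("layer", "complex"):
        raise ValueError("stratum must be 'layer' or 'complex'")
    rec_by_id = {r.sample_id: r for r in records}
    missing = [i.sample_id for i in ids if i.sample_id not in rec_by_id]
    if missing:
        raise ValueError(f"identifications without metadata records: {sorted(missing)}")
    cells: dict[tuple[str, str], int] = {}
    fail_cells: dict[str, int] = {}
    strata_seen: list[str] = []
    for ident in ids:
        s = getattr(rec_by_id[ident.sample_id], stratum)
        if s not in strata_seen:
            strata_seen.append(s)
        if ident.identified:
            cells[(ident.category, s)] = cells.get((ident.category, s), 0) + 1
        else:
            fail_cells[s] = fail_cells.get(s, 0) + 1
    categories = sorted({c for c, _ in cells})
    counts = pd.DataFrame(0, index=categories, columns=strata_seen, dtype=int)
    for (c, s), n in cells.items():
        counts.loc[c, s] = n
    fails = pd.Series({s: fail_cells.get(s, 0) for s in strata_seen}, dtype=int)
    return ZNISPTable(counts, fails)


def success_rate(t: ZNISPTable, stratum: str | None = None) -> int:
    """Headline identification success rate, percent rounded half-up.

    With ``stratum=None`` the rate is over all strata combined.
    """
    if stratum is None:
        total, fail = int(t.totals().sum()), int(t.fails.sum())
    else:
        if stratum not in t.strata:
            raise KeyError(f"unknown stratum {stratum!r}")
        total, fail = int(t.totals()[stratum]), int(t.fails[stratum])
    if total == 0:
        raise ValueError("empty stratum has no success rate")
    return int(round_half_up(100.0 * (total - fail) / total))


def map_broad(t: ZNISPTable, mapping: dict[str, str]) -> ZNISPTable:
    """Sum categories into broad faunal categories; ZNISP is conserved."""
    unmapped = [c for c in t.counts.index if c not in mapping]
    if unmapped:
        raise KeyError(f"categories without a broad mapping: {unmapped}")
    broad = t.counts.groupby([mapping[c] for c in t.counts.index]).sum()
    out = ZNISPTable(broad, t.fails.copy())
    assert out.counts.to_numpy().sum() == t.counts.to_numpy().sum()
    return out


@dataclass
class ComparisonTable:
    """ZooMS vs morphological NISP per broad category x complex.

    ``table`` carries counts and the three percentage series (ZooMS %,
    morphology %, combined-total %); ``stats`` holds, per complex, the
    Spearman rank correlation with a permutation p-value and the OLS slope
    of morphology counts on ZooMS counts.
    """

    table: pd.DataFrame
    stats: pd.DataFrame


def compare_with_morph(
    z: ZNISPTable,
    morph: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ComparisonTable:
    """Combine a broad-category ZNISP table with morphological NISP counts.

    ``morph`` must be indexed by the same broad categories with the same
    stratum columns.  The association per complex is the Spearman rank
    correlation (p-value from seeded permutations of the morphology column)
    plus an ordinary least-squares slope on the raw counts.
    """
    from scipy.stats import spearmanr
    import statsmodels.api as sm

    if set(morph.index) != set(z.counts.index) or list(morph.columns) != z.strata:
        raise ValueError("morphology table must cover the same broad categories and strata")
    morph = morph.reindex(z.counts.index)

    rows = []
    for s in z.strata:
        zn, mo = z.counts[s], morph[s]
        total = zn + mo
        rows.append(
            pd.DataFrame(
                {
                    "complex": s,
                    "category": z.counts.index,
                    "znisp": zn.to_numpy(),
                    "morph_nisp": mo.to_numpy(),
                    "total": total.to_numpy(),
                    "znisp_pct": [round_half_up(v, 1) for v in 100 * zn / max(zn.sum(), 1)],
                    "morph_pct": [round_half_up(v, 1) for v in 100 * mo / max(mo.sum(), 1)],
                    "total_pct": [round_half_up(v, 1) for v in 100 * total / max(total.sum(), 1)],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)

    rng = np.random.default_rng(seed)
    stats_rows = []
    for s in z.strata:
        zn, mo = z.counts[s].to_numpy(float), morph[s].to_numpy(float)
        if np.ptp(zn) == 0 or np.ptp(mo) == 0:
            # a constant series carries no rank information
            rho, p = float("nan"), float("nan")
        else:
            rho = spearmanr(zn, mo).statistic
            perm = np.empty(n_permutations)
            for k in range(n_permutations):
                perm[k] = spearmanr(zn, rng.permutation(mo)).statistic
            p = float((np.sum(np.abs(perm) >= abs(rho)) + 1) / (n_permutations + 1))
        ols = sm.OLS(mo, sm.add_constant(zn)).fit()
        stats_rows.append(
            {"complex": s, "spearman_rho": float(rho), "perm_pvalue": p,
             "ols_slope": float(ols.params[1])}
        )
    return ComparisonTable(table=table, stats=pd.DataFrame(stats_rows).set_index("complex"))


@dataclass
class SuccessGrid:
    """Per-square (optionally per square x layer) identification success.

    ``grid`` columns: n_sampled, n_identified, percent.  Cells that were
    never sampled are simply absent from the index (never shown as 0%).
    """

    grid: pd.DataFrame
    by_layer: bool = False

    def percent(self, key) -> float:
        return float(self.grid.loc[key, "percent"])


def spatial_success(
    ids: list[Identification],
    records: list[SampleRecord],
    by_layer: bool = False,
) -> SuccessGrid:
    """Success-rate grid over excavation squares.

    Records without a square label are excluded from the grid (they are
    reported in the ``n_no_square`` attribute of the frame).
    """
    rec_by_id = {r.sample_id: r for r in records}
    rows = []
    n_no_square = 0
    for ident in ids:
        rec = rec_by_id.get(ident.sample_id)
        if rec is None or rec.square is None:
            n_no_square += 1
            continue
        key = (rec.square, rec.layer) if by_layer else rec.square
        rows.append((key, ident.identified))
    df = pd.DataFrame(rows, columns=["key", "identified"])
    if df.empty:
        grid = pd.DataFrame(columns=["n_sampled", "n_identified", "percent"])
    else:
        g = df.groupby("key")["identified"]
        grid = pd.DataFrame({"n_sampled": g.size(), "n_identified": g.sum().astype(int)})
        grid["percent"] = 100.0 * grid["n_identified"] / grid["n_sampled"]
        if by_layer:
            grid.index = pd.MultiIndex.from_tuples(grid.index, names=["square", "layer"])
    out = SuccessGrid(grid=grid, by_layer=by_layer)
    out.grid.attrs["n_no_square"] = n_no_square
    return out


def plot_success_grid(grid: SuccessGrid, path: str | Path) -> Path:
    """Plain heatmap export (squares as letter x number grid) to PNG/PDF."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = grid.grid
    idx = g.index.get_level_values(0) if grid.by_layer else g.index
    letters = sorted({str(s)[0] for s in idx})
    numbers = sorted({str(s)[1:] for s in idx})
    mat = np.full((len(letters), len(numbers)), np.nan)
    pct = g.groupby(idx)["n_identified"].sum() / g.groupby(idx)["n_sampled"].sum() * 100
    for sq, v in pct.items():
        mat[letters.index(str(sq)[0]), numbers.index(str(sq)[1:])] = v
    fig, ax = plt.subplots(figsize=(1.2 * len(numbers) + 2, 1.0 * len(letters) + 1.5))
    im = ax.imshow(mat, vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(numbers)), numbers)
    ax.set_yticks(range(len(letters)), letters)
    for i in range(len(letters)):
        for j in range(len(numbers)):
            if not np.isnan(mat[i, j]):
                ax.text(j, i, f"{mat[i, j]:.0f}", ha="center", va="center", color="w")
    fig.colorbar(im, label="ZooMS success (%)")
    ax.set_title("Identification success by excavation square")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# packaged fixtures (published assemblage counts)


def _read_packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("zoomsid.data").joinpath(name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#", index_col=0)


def load_znisp_fixture() -> ZNISPTable:
    """Published ZNISP counts per category x cultural complex."""
    df = _read_packaged_csv("castelcivita_znisp.csv")
    fails = df.loc[FAIL]
    counts = df.drop(index=FAIL)
    return ZNISPTable(counts, fails)


def load_morph_fixture() -> pd.DataFrame:
    """Transcribed morphological NISP per broad category x complex (see the
    file header: comparison-grade only, not exact fixture counts)."""
    return _read_packaged_csv("castelcivita_morph_broad.csv")


def load_broad_map() -> dict[str, str]:
    """Published mapping from reported ZooMS category to broad faunal category."""
    ref = resources.files("zoomsid.data").joinpath("broad_categories.json")
    return json.loads(ref.read_text())


def expand_fixture(
    t: ZNISPTable | None = None, prefix: str = "FIX"
) -> tuple[list[Identification], list[SampleRecord]]:
    """Reconstruct per-sample identifications/records realizing a ZNISP table.

    Inverse of :func:`tabulate_znisp` up to sample identity: tabulating the
    result reproduces the fixture counts exactly.  Layer labels are the
    canonical layer of each complex (cgr / pie / rsa').
    """
    if t is None:
        t = load_znisp_fixture()
    layer_of = {"Mousterian": "cgr", "Uluzzian": "pie", "Protoaurignacian": "rsa'"}
    ids: list[Identification] = []
    records: list[SampleRecord] = []
    k = 0
    full = t.with_fail_row()
    for stratum in t.strata:
        for category, n in full[stratum].items():
            for _ in range(int(n)):
                k += 1
                sid = f"{prefix}{k:04d}"
                records.append(
                    SampleRecord(sid, layer=layer_of.get(stratum, "cgr"), complex=stratum)
                )
                if category == FAIL:
                    ids.append(Identification(sid, "fail", None, 0, "single"))
                else:
                    ids.append(Identification(sid, "identified", category, 9, "full"))
    return ids, records
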