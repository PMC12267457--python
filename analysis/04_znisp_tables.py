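"""ZNISP tables and success rates from the published assemblage counts.

Loads the packaged transcription of the site's per-complex ZNISP counts,
recomputes percentages and headline identification success rates, maps the
reported categories onto broad faunal categories, and writes the tables
under results/.
"""

from pathlib import Path

from zoomsid.assemblage import (
    load_broad_map,
    load_znisp_fixture,
    map_broad,
    success_rate,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    t = load_znisp_fixture()

    print("per-complex totals:", dict(t.totals()))
    print(f"identified {int(t.identified().sum())} of {int(t.totals().sum())} sampled bones")
    for stratum in t.strata:
        print(f"  {stratum:>17}: success rate {success_rate(t, stratum)}%")
    print(f"  {'overall':>17}: success rate {success_rate(t)}%")

    pct = t.percentages()
    pct.to_csv(RESULTS / "znisp_percentages.csv")

    broad = map_broad(t, load_broad_map())
    broad.with_fail_row().to_csv(RESULTS / "znisp_broad_counts.csv")
    by_cat = broad.counts.sum(axis=1).sort_values(ascending=False)
    print("\nbroad-category ZNISP totals:")
    for cat, n in by_cat.items():
        print(f"  {cat:>12}: {n}")
    print(f"wrote {RESULTS/'znisp_percentages.csv'} and {RESULTS/'znisp_broad_counts.csv'}")


if __name__ == "__main__":
    main()
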