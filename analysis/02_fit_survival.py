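"""Fit six parametric families to the active arm's PFS and OS.

Ranks the families by AIC (BIC alongside) for each endpoint and serializes
the log-normal fits — the family the economic model extrapolates with, per
the selection policy of combining information criteria with visual
inspection of the extrapolated tail — to results/fits.json.  Rank tables go
to results/survfit_{pfs,os}.csv.
"""
from pathlib import Path

from psmcea import survfit
from psmcea.ipd import read_ipd

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ipd = read_ipd(OUT / "ipd.csv")
    active = ipd[ipd["arm"] == "active"]
    chosen = {}
    for endpoint in ("pfs", "os"):
        t, e = active[f"{endpoint}_time"], active[f"{endpoint}_event"]
        fits = {f: survfit.fit_parametric(t, e, f) for f in survfit.FAMILIES}
        table = survfit.rank_fits(fits.values())
        table.to_csv(OUT / f"survfit_{endpoint}.csv", index=False)
        print(f"\n{endpoint.upper()} fits (ranked by AIC):")
        print(table.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
        chosen[f"{endpoint}_active"] = fits["lognormal"]
    survfit.save_fits(chosen, OUT / "fits.json")
    print(f"\nserialized log-normal fits -> {OUT / 'fits.json'}")


if __name__ == "__main__":
    main()
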