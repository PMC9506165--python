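"""Plot the analysis outputs: salt surfaces, cohort curves, excess mortality.

Reads the CSVs written by the earlier steps and saves PNG figures under
--out-dir/figures. Purely a convenience layer; nothing downstream consumes
the images.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    figdir = args.out_dir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    salt = pd.read_csv(args.out_dir / "salt_surface.csv")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, sex in zip(axes, ("male", "female")):
        sub = salt[(salt.sex == sex) & (salt.age >= 20)]
        for year in (1950, 1970, 1990, 2010):
            s = sub[sub.year == year].sort_values("age")
            ax.step(s.age, s.grams_per_day, where="mid", label=str(year))
        ax.set_title(sex)
        ax.set_xlabel("age")
    axes[0].set_ylabel("salt intake (g/day)")
    axes[0].legend(title="year")
    fig.tight_layout()
    fig.savefig(figdir / "salt_by_age.png", dpi=150)

    curves = pd.read_csv(args.out_dir / "cohort_curves.csv")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, sex in zip(axes, ("male", "female")):
        for scen, style in (("base", "-"), ("0pct_effect", "--")):
            sub = curves[(curves.sex == sex) & (curves.scenario == scen)]
            for cohort, grp in sub.groupby("cohort"):
                ax.plot(
                    grp.year,
                    grp.cvd_rate_per_1000,
                    style,
                    label=f"C{cohort} {scen}" if sex == "male" else None,
                )
        ax.set_yscale("log")
        ax.set_title(sex)
        ax.set_xlabel("calendar year")
    axes[0].set_ylabel("CVD mortality (per 1000 person-years)")
    fig.tight_layout()
    fig.savefig(figdir / "cohort_curves.png", dpi=150)

    excess = pd.read_csv(args.out_dir / "excess_by_year.csv")
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for j, sex in enumerate(("male", "female")):
        for scen, grp in excess[excess.sex == sex].groupby("scenario"):
            axes[0, j].plot(grp.year, grp.absolute_excess, label=scen)
            axes[1, j].plot(grp.year, grp.relative_excess_pct, label=scen)
        axes[0, j].set_title(sex)
        axes[1, j].set_xlabel("calendar year")
    axes[0, 0].set_ylabel("absolute excess (persons/yr)")
    axes[1, 0].set_ylabel("relative excess (%)")
    axes[0, 1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(figdir / "excess_mortality.png", dpi=150)

    print(f"wrote figures to {figdir}/")


if __name__ == "__main__":
    main()
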