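"""Figures and tables mirroring the presentation of the analysis.

Every figure has a CSV twin holding exactly the plotted numbers, so no
value exists only in a figure.
"""

from __future__ import annotations

import pathlib

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import ResultBundle  # noqa: E402

_AGE_COLOURS = {"young": "#4878a8", "old": "#b0544e"}


def _save(fig, data: pd.DataFrame, outdir: pathlib.Path, name: str
          ) -> tuple[str, str]:
    fig_path = outdir / f"{name}.png"
    csv_path = outdir / f"{name}.csv"
    fig.savefig(fig_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    data.to_csv(csv_path, index=False)
    return str(fig_path), str(csv_path)


def plot_apa_profiles(bundle: ResultBundle, outdir: pathlib.Path,
                      measure: str) -> tuple[str, str]:
    """Mean apa per subunit, young vs old, with zone boundaries."""
    m = f"apa_{measure[:5]}"
    prof = bundle.profiles[bundle.profiles["measure"] == m]
    mean = (prof.groupby(["age_group", "subunit"])["value"]
            .mean().reset_index())
    fig, ax = plt.subplots(figsize=(7, 3.5))
    width = 0.4
    for k, age in enumerate(("young", "old")):
        sel = mean[mean["age_group"] == age]
        ax.bar(sel["subunit"] + (k - 0.5) * width, sel["value"],
               width=width, label=age, color=_AGE_COLOURS[age])
    ax.set_xlabel("proportional subunit")
    ax.set_ylabel(f"apa.{measure[:5]} (%)")
    ax.set_title(f"{bundle.config.fold_type}: {measure} amounts per area")
    ax.legend()
    return _save(fig, mean, outdir, f"apa_{measure}_profile")


def plot_demarcation(bundle: ResultBundle, outdir: pathlib.Path
                     ) -> tuple[str, str]:
    """Per-boundary demarcation classification as a bar diagram."""
    dem = bundle.demarcation.copy()
    colour = {"distinct": "#333333", "continuous": "#999999",
              "none": "#eeeeee"}
    rows = dem[["age_group", "measure"]].drop_duplicates().values.tolist()
    fig, ax = plt.subplots(figsize=(8, 0.6 * len(rows) + 1))
    for y, (age, measure) in enumerate(rows):
        sel = dem[(dem["age_group"] == age) & (dem["measure"] == measure)]
        for _, r in sel.iterrows():
            ax.barh(y, 1, left=r["boundary"] - 0.5, height=0.6,
                    color=colour[r["classification"]],
                    edgecolor="white")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([f"{a}/{m}" for a, m in rows])
    ax.set_xlabel("subunit boundary")
    ax.set_title("Demarcation summary (dark = distinct, grey = continuous)")
    return _save(fig, dem, outdir, "demarcation")


def plot_median_scores(bundle: ResultBundle, outdir: pathlib.Path
                       ) -> tuple[str, str]:
    """Median collagen diameter scores per subunit; gaps stay gaps."""
    med = bundle.median_scores
    cats = [c for c in med.columns if c not in ("subunit", "age_group")]
    fig, axes = plt.subplots(len(cats), 1, figsize=(7, 2.2 * len(cats)),
                             sharex=True)
    for ax, cat in zip(axes, cats):
        for age in ("young", "old"):
            sel = med[med["age_group"] == age]
            ax.plot(sel["subunit"], sel[cat], "o", label=age,
                    color=_AGE_COLOURS[age])
        ax.set_ylabel(f"{cat}\nscore")
        ax.set_ylim(-0.3, 3.3)
    axes[0].legend()
    axes[-1].set_xlabel("proportional subunit")
    tidy = med.melt(id_vars=["subunit", "age_group"],
                    var_name="category", value_name="median_score")
    return _save(fig, tidy, outdir, "median_scores")


def render_report(bundle: ResultBundle, outdir) -> dict[str, str]:
    """Write all figures (PNG) and their CSV twins for one bundle."""
    if bundle.profiles.empty:
        raise ValueError("bundle has no profile data to report")
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for measure in ("collagen", "elastic"):
        fig_p, csv_p = plot_apa_profiles(bundle, outdir, measure)
        paths[f"apa_{measure}"] = fig_p
        paths[f"apa_{measure}_csv"] = csv_p
    fig_p, csv_p = plot_demarcation(bundle, outdir)
    paths["demarcation"] = fig_p
    paths["demarcation_csv"] = csv_p
    fig_p, csv_p = plot_median_scores(bundle, outdir)
    paths["median_scores"] = fig_p
    paths["median_scores_csv"] = csv_p
    return paths
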