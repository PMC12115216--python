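"""Population statistics: Mann-Whitney comparisons and PCA on coefficients.

Compares the test populations on J-index, aspect ratio, solidity and the
four curvature statistics (two-sided Mann-Whitney, compact letter display),
then runs covariance PCA over the 32 Fourier coefficients with group
centroids and 95% confidence ellipses for the group means.

Writes ``results/comparisons.csv``, ``results/pca_scores.csv``,
``results/pca_loadings.csv`` and an SVG score plot.
"""

import matplotlib

matplotlib.use("SVG")
import matplotlib.pyplot as plt
import pandas as pd

from seedmorph.stats import compare_groups, pca_fourier

from common import RESULTS, TEST_POPULATIONS


def main() -> None:
    meas = pd.read_csv(RESULTS / "measurements.csv")
    curv = pd.read_csv(RESULTS / "curvature.csv")
    jidx = pd.read_csv(RESULTS / "jindex.csv")
    coeffs = pd.read_csv(RESULTS / "coefficients.csv")

    by_group = {}
    for label in TEST_POPULATIONS:
        m = meas[meas["population"] == label]
        c = curv[curv["population"] == label]
        j = jidx[jidx["population"] == label]
        by_group[label] = {
            "J_heben": j[j["model"] == "heben"]["J"].to_numpy(),
            "J_chenin": j[j["model"] == "chenin"]["J"].to_numpy(),
            "AR": m["aspect_ratio"].to_numpy(),
            "S": m["solidity"].to_numpy(float),
            "Max": c["max_curv"].to_numpy(),
            "Min": c["min_curv"].to_numpy(),
            "Mean": c["mean_curv"].to_numpy(),
            "Ratio": c["max_to_mean_ratio"].to_numpy(),
        }
    comparisons = compare_groups(by_group)
    rows = []
    for metric, res in comparisons.items():
        for g in res.groups:
            rows.append({"metric": metric, "population": g, "mean": res.means[g],
                         "cv": res.cvs[g], "letters": res.letters[g]})
        for (gi, gj), p in res.p_values.items():
            rows.append({"metric": metric, "population": f"{gi} vs {gj}",
                         "U": res.u_stats[(gi, gj)], "p": p})
    pd.DataFrame(rows).to_csv(RESULTS / "comparisons.csv", index=False, float_format="%.6g")
    for metric in ("S", "Min", "Ratio"):
        res = comparisons[metric]
        shown = ", ".join(f"{g}: {res.means[g]:.3g}{res.letters[g]}" for g in res.groups)
        print(f"{metric:6s} {shown}")

    table = coeffs[coeffs["population"].isin(TEST_POPULATIONS)].set_index("seed_id")
    pca = pca_fourier(table, group_labels=table["population"])
    pca.scores.to_csv(RESULTS / "pca_scores.csv", float_format="%.6f")
    pca.loadings.to_csv(RESULTS / "pca_loadings.csv", float_format="%.6f")
    vf = pca.variance_fractions
    print(f"\nPC1 {100 * vf[0]:.1f}% of variation, PC2 {100 * vf[1]:.1f}%")

    fig, ax = plt.subplots(figsize=(6, 5))
    for (g, sub), color in zip(pca.scores.groupby("group"), ("tab:red", "tab:blue", "tab:green")):
        ax.scatter(sub["PC1"], sub["PC2"], s=14, color=color, label=g, alpha=0.7)
        ax.scatter(*pca.centroids[g], marker="s", s=60, color=color, edgecolor="k", zorder=5)
        if g in pca.ellipses:
            ax.plot(*pca.ellipses[g].boundary().T, color=color, lw=1.2)
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}%)")
    ax.legend(frameon=False)
    ax.set_title("Fourier-coefficient PCA: centroids and 95% mean ellipses")
    fig.tight_layout()
    fig.savefig(RESULTS / "pca_scores.svg")
    print(f"figure -> {RESULTS / 'pca_scores.svg'}")


if __name__ == "__main__":
    main()
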