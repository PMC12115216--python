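"""End-to-end orchestration: inputs -> measurements -> Acs/models -> J-index
-> groups -> curvature -> statistics, with reproducible CSV outputs.

Every constant of the analysis (J thresholds 90/94, AR boundary 1.575,
8 harmonics, curvature window [0.2, 0.8]) lives on :class:`PipelineConfig`
with the study's values as defaults. A run writes its full configuration
and package version to ``run_log.json`` so outputs are auditable; rerunning
with the same config and seed is bit-identical on the CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seedmorph import __version__
from seedmorph.classify import AR_BOUNDARY, J_HIGH, J_LOW, assign_group, order_by_solidity, split_by_aspect_ratio
from seedmorph.contours import SeedContour, extract_contours, read_tps
from seedmorph.curvature import DEFAULT_DEGREE, DEFAULT_T_RANGE, contour_curvature_profile
from seedmorph.descriptors import measure
from seedmorph.efd import AverageContour, average_contour, build_model, efd_transform, normalize_coeffs
from seedmorph.jindex import jindex_population
from seedmorph.stats import compare_groups, pca_fourier
from seedmorph.synthetic import build_template, population_contours, sample_population

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_POPULATIONS", "DEFAULT_MODELS"]

# synthetic-mode defaults mirror the study design: two reference populations
# per model (30/20 and 20/20 seeds) plus one test population per morphotype
DEFAULT_POPULATIONS: dict[str, tuple[str, int]] = {
    "heben_2020": ("heben_like", 30),
    "heben_2024": ("heben_like", 20),
    "chenin": ("chenin_like", 20),
    "gewurztraminer": ("chenin_like", 20),
    "heben_test": ("heben_like", 25),
    "chenin_test": ("chenin_like", 25),
    "sylvestris_test": ("sylvestris_like", 25),
}
DEFAULT_MODELS: dict[str, list[str]] = {
    "heben": ["heben_2020", "heben_2024"],
    "chenin": ["chenin", "gewurztraminer"],
}


@dataclass
class PipelineConfig:
    input_mode: str = "synthetic"  # synthetic | images | tps
    input_paths: dict[str, str] = field(default_factory=dict)  # population label -> file
    populations: dict[str, tuple[str, int]] = field(default_factory=lambda: dict(DEFAULT_POPULATIONS))
    model_definitions: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_MODELS))
    px_per_mm: float = 20.0
    n_harmonics: int = 8
    n_points: int = 360
    coeff_noise_cv: float = 0.05
    size_cv: float = 0.03
    j_low: float = J_LOW
    j_high: float = J_HIGH
    ar_boundary: float = AR_BOUNDARY
    curvature_degree: int = DEFAULT_DEGREE
    curvature_t_range: tuple[float, float] = DEFAULT_T_RANGE
    rng_seed: int = 0
    out_dir: str | None = None
    score_populations: list[str] | None = None  # None -> score every population

    def validate(self) -> None:
        if self.input_mode not in ("synthetic", "images", "tps"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if not self.j_low < self.j_high:
            raise ValueError("j_low must be below j_high")
        for name, numeric in (("px_per_mm", self.px_per_mm), ("n_harmonics", self.n_harmonics),
                              ("n_points", self.n_points)):
            if numeric <= 0:
                raise ValueError(f"{name} must be positive")


def _load_populations(config: PipelineConfig) -> dict[str, list[SeedContour]]:
    """Stage 1: resolve input contours per population label."""
    if config.input_mode == "synthetic":
        if not config.populations:
            raise ValueError("extraction stage: synthetic mode needs a populations mapping")
        # stable per-population child seeds below 2**31
        root = np.random.default_rng(config.rng_seed)
        labels = sorted(config.populations)
        child = {lab: int(s) for lab, s in zip(labels, root.integers(0, 2**31 - 1, size=len(labels)))}
        out = {}
        for label in labels:
            morphotype, n = config.populations[label]
            pop = sample_population(build_template(morphotype), n, config.coeff_noise_cv,
                                    config.size_cv, rng_seed=child[label])
            contours = population_contours(pop, config.n_points)
            for c in contours:
                c.source_id = f"{label}_{c.source_id.rsplit('_', 1)[-1]}"
            out[label] = contours
        return out
    if not config.input_paths:
        raise ValueError(f"extraction stage: no input files configured for mode {config.input_mode!r}")
    out = {}
    for label, path in sorted(config.input_paths.items()):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"extraction stage: missing input {p}")
        if config.input_mode == "tps":
            out[label] = read_tps(p)
        else:
            import imageio.v3 as iio

            contours = extract_contours(iio.imread(p), config.px_per_mm)
            if not contours:
                raise ValueError(f"extraction stage: no contours found in {p}")
            out[label] = contours
        for i, c in enumerate(out[label]):
            c.source_id = f"{label}_{i:03d}"
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write CSV outputs if ``config.out_dir`` is set."""
    config.validate()
    contours_by_pop = _load_populations(config)
    true_morphotype = {lab: spec[0] for lab, spec in config.populations.items()} if config.input_mode == "synthetic" else {}

    # stage 2: per-seed measurements
    meas_rows = []
    measurements = {}
    for label, contours in contours_by_pop.items():
        ms = [measure(c) for c in contours]
        measurements[label] = ms
        for m in ms:
            meas_rows.append({"population": label, **{"seed_id": m.source_id}, **m.as_dict()})
    measurements_df = pd.DataFrame(meas_rows)

    # stage 3: per-seed normalized coefficients and per-population Acs
    coeffs_by_pop = {
        label: [normalize_coeffs(efd_transform(c, config.n_harmonics)) for c in contours]
        for label, contours in contours_by_pop.items()
    }
    acs: dict[str, AverageContour] = {
        label: average_contour(cs, label, config.n_points) for label, cs in coeffs_by_pop.items()
    }
    coeff_rows = []
    for label, cs in coeffs_by_pop.items():
        for c, contour in zip(cs, contours_by_pop[label]):
            row = {"population": label, "seed_id": contour.source_id, "size_mm": c.size_mm}
            names = [f"{ch}{k}" for ch in "ABCD" for k in range(1, config.n_harmonics + 1)]
            row.update(dict(zip(names, c.flat())))
            coeff_rows.append(row)
    coeffs_df = pd.DataFrame(coeff_rows)

    # stage 4: reference models from Acs
    models = {}
    for name, members in config.model_definitions.items():
        missing = [m for m in members if m not in acs]
        if missing:
            raise ValueError(f"model stage: model {name!r} references unknown population(s) {missing}")
        models[name] = build_model([acs[m] for m in members], name, config.n_points)

    # stage 5: J-index of the scored populations against every model
    if config.score_populations is None:
        scored = sorted(contours_by_pop)
    else:
        unknown = [s for s in config.score_populations if s not in contours_by_pop]
        if unknown:
            raise ValueError(f"jindex stage: unknown score_populations {unknown}")
        scored = sorted(config.score_populations)
    jindex_rows = []
    j_by_pop_model: dict[str, dict[str, float]] = {}
    per_seed_j: dict[str, dict[str, list[float]]] = {}
    for label in scored:
        contours = contours_by_pop[label]
        j_by_pop_model[label] = {}
        per_seed_j[label] = {}
        for mname, model in models.items():
            res = jindex_population(model, contours, population_label=label)
            j_by_pop_model[label][mname] = res.mean_j
            per_seed_j[label][mname] = res.per_seed
            for sid, j, pose in zip(res.seed_ids, res.per_seed, res.poses):
                jindex_rows.append({"population": label, "model": mname, "seed_id": sid, "J": j,
                                    "dx": pose.dx, "dy": pose.dy,
                                    "theta_deg": float(np.rad2deg(pose.rotation)), "scale": pose.scale})
    jindex_df = pd.DataFrame(jindex_rows)

    # stage 6: ordering and group assignment (population level, as for cultivars)
    model_names = list(config.model_definitions)
    m_heben, m_chenin = model_names[0], model_names[1] if len(model_names) > 1 else model_names[0]
    pop_ar = {label: float(np.mean([m.aspect_ratio for m in measurements[label]])) for label in scored}
    pop_s = {label: float(np.mean([m.solidity for m in measurements[label]])) for label in scored}
    ar_class = split_by_aspect_ratio(pop_ar, config.ar_boundary)
    ranks = order_by_solidity({lab: (ar_class[lab], pop_s[lab]) for lab in pop_ar})
    group_rows = []
    groups: dict[str, str] = {}
    for label in scored:
        jh, jc = j_by_pop_model[label][m_heben], j_by_pop_model[label][m_chenin]
        g = assign_group(jh, jc, j_low=config.j_low, j_high=config.j_high)
        groups[label] = g
        group_rows.append({"population": label, "true_morphotype": true_morphotype.get(label, ""),
                           "J_heben": jh, "J_chenin": jc, "AR": pop_ar[label], "S": pop_s[label],
                           "ar_class": ar_class[label], "rank": ranks[label], "group": g})
    groups_df = pd.DataFrame(group_rows).sort_values("rank").reset_index(drop=True)

    # stage 7: per-seed curvature statistics on the standard-orientation outline
    curv_rows = []
    curvature: dict[str, list] = {}
    for label in scored:
        cs = coeffs_by_pop[label]
        profs = []
        for c, contour in zip(cs, contours_by_pop[label]):
            from seedmorph.efd import reconstruct

            std = reconstruct(c, config.n_points, at_scale=True, source_id=contour.source_id)
            prof = contour_curvature_profile(std, config.curvature_degree, config.curvature_t_range)
            profs.append(prof)
            curv_rows.append({"population": label, "seed_id": contour.source_id,
                              "max_curv": prof.max_curv, "min_curv": prof.min_curv,
                              "mean_curv": prof.mean_curv, "max_to_mean_ratio": prof.max_to_mean_ratio,
                              "degree": prof.degree, "rms_residual": prof.rms_residual})
        curvature[label] = profs
    curvature_df = pd.DataFrame(curv_rows)

    # stage 8: group statistics and PCA over the Fourier coefficients
    by_group: dict[str, dict[str, list[float]]] = {}
    for label in scored:
        ms = measurements[label]
        d = by_group.setdefault(label, {})
        d["J_heben"] = per_seed_j[label][m_heben]
        d["J_chenin"] = per_seed_j[label][m_chenin]
        d["AR"] = [m.aspect_ratio for m in ms]
        d["S"] = [float(m.solidity) for m in ms]
        d["Max"] = [p.max_curv for p in curvature[label]]
        d["Min"] = [p.min_curv for p in curvature[label]]
        d["Mean"] = [p.mean_curv for p in curvature[label]]
        d["Ratio"] = [p.max_to_mean_ratio for p in curvature[label]]
    comparisons = compare_groups(by_group) if len(by_group) >= 2 else {}
    comp_rows = []
    for metric, res in comparisons.items():
        for g in res.groups:
            comp_rows.append({"metric": metric, "population": g, "mean": res.means[g],
                              "cv": res.cvs[g], "letters": res.letters[g]})
        for (gi, gj), p in res.p_values.items():
            comp_rows.append({"metric": metric, "population": f"{gi} vs {gj}",
                              "U": res.u_stats[(gi, gj)], "p": p})
    comparisons_df = pd.DataFrame(comp_rows)
    pca_table = coeffs_df[coeffs_df["population"].isin(scored)].set_index("seed_id")
    pca = pca_fourier(pca_table, group_labels=pca_table["population"])

    report = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "measurements": measurements_df,
        "coefficients": coeffs_df,
        "acs": acs,
        "models": models,
        "jindex": jindex_df,
        "groups": groups_df,
        "group_of": groups,
        "curvature": curvature_df,
        "comparisons": comparisons,
        "comparisons_table": comparisons_df,
        "pca": pca,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("measurements", measurements_df), ("coefficients", coeffs_df),
                         ("jindex", jindex_df), ("groups", groups_df), ("curvature", curvature_df),
                         ("comparisons", comparisons_df)):
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
        pca.scores.to_csv(out / "pca_scores.csv", float_format="%.6f")
        pca.loadings.to_csv(out / "pca_loadings.csv", float_format="%.6f")
        model_rows = []
        for name, model in models.items():
            row = {"model": name, "members": "|".join(model.member_labels), "size_mm": model.coeffs.size_mm}
            names = [f"{ch}{k}" for ch in "ABCD" for k in range(1, config.n_harmonics + 1)]
            row.update(dict(zip(names, model.coeffs.flat())))
            model_rows.append(row)
        pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False, float_format="%.10f")
        log = {"config": dataclasses.asdict(config), "version": __version__,
               "variance_fractions": [float(v) for v in pca.variance_fractions[:5]],
               "groups": {r["population"]: r["group"] for r in group_rows}}
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return report
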