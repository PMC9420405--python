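"""End-to-end analysis: from a craniometric table to every summary statistic.

Chains the pipeline stages in the canonical order — preprocessing,
two-block PLS, factor (size/shape) model, RMA trajectory fits and
contrasts, heterochrony decomposition, encephalization associations and
the measurement-error robustness check — and collects the results in one
object with CSV export.  The numbered scripts under ``analysis/``, the
command-line interface and the acceptance script are all thin layers over
:func:`run_analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, factors, heterochrony, pls, preprocess, robustness
from .datasets import Dataset, subset_complete
from .errors import FitError, ValidationError


@dataclass
class AnalysisOptions:
    pls_mode: str = "correlation"
    n_factors: int = 2
    slope_ci_method: str = "analytic"
    intercept_ci_method: str = "bootstrap"
    eq_a: float = 1.77
    eq_b: float = 0.76
    deadband: float = 0.1
    reference_group: str = "great_ape"  # reference ontogenetic trajectory
    ape_group: str = "great_ape"
    robust_error: float = 0.05
    robust_reps: int = 500
    n_robust_specimens: int = 3
    seed: int = 0


@dataclass
class AnalysisResult:
    options: AnalysisOptions
    pls_model: pls.PLSModel
    factor_model: factors.FactorModel
    isometry: factors.IsometryAngles
    taxon_fits: dict[str, allometry.RMAFit]  # factor-plane, per extant taxon
    group_fits: dict[str, allometry.RMAFit]  # factor-plane, adult subsets
    pls_fits: dict[str, allometry.RMAFit]  # PLS-plane, apes vs hominins
    pls_slope_test: allometry.SlopeComparison | None
    pls_intercepts: allometry.InterceptComparison | None
    angles: dict[str, allometry.TrajectoryAngle]
    decompositions: dict[str, heterochrony.TrajectoryDecomposition]
    associations: dict[str, heterochrony.AssocResult]
    partials: dict[str, heterochrony.PartialCorrelation]
    geo_age_correlation: tuple[float, float] | None
    robustness_results: list[robustness.PerturbationResult]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=isinstance(table.index, pd.MultiIndex)
                         or table.index.name is not None)


def _extant_taxa(ds: Dataset) -> list[str]:
    """Taxa represented by both juveniles and adults, in appearance order."""
    frame = ds.to_frame()
    out = []
    for taxon, sub in frame.groupby("taxon", sort=False):
        stages = set(sub["age_class"])
        if {"adult", "juvenile"} <= stages:
            out.append(str(taxon))
    return out


def run_analysis(ds: Dataset, options: AnalysisOptions | None = None) -> AnalysisResult:
    opt = options or AnalysisOptions()
    frame = ds.to_frame().set_index("specimen_id")

    # --- ordinations -------------------------------------------------------
    shape = preprocess.gm_scale(ds)
    logm = preprocess.log_transform(ds)
    pls_model = pls.fit_pls(shape, ds.block_map, mode=opt.pls_mode)
    fmodel = factors.fit_factors(logm, k=opt.n_factors)
    iso = factors.isometry_angle(fmodel) if opt.n_factors == 2 else None

    scores = fmodel.scores
    f1 = scores["factor1"].to_numpy()
    f2 = scores["factor2"].to_numpy()
    taxa = frame["taxon"].to_numpy()
    groups = frame["group"].to_numpy()
    stages = frame["age_class"].to_numpy()

    # trajectory fits regress the shape factor (I) on the size factor (II):
    # the slope is the shape change per unit size along the trajectory
    def rma(mask, x_label="factor2", y_label="factor1", xs=f2, ys=f1):
        return allometry.fit_rma(
            xs[mask], ys[mask], x_label=x_label, y_label=y_label,
            slope_ci_method=opt.slope_ci_method,
            intercept_ci_method=opt.intercept_ci_method, seed=opt.seed,
        )

    # --- factor-plane RMA: extant taxa (adults + juveniles) ---------------
    taxon_fits: dict[str, allometry.RMAFit] = {}
    for taxon in _extant_taxa(ds):
        mask = taxa == taxon
        if mask.sum() >= 3:
            taxon_fits[taxon] = rma(mask)

    # --- factor-plane RMA: adult subsets ----------------------------------
    group_fits: dict[str, allometry.RMAFit] = {}
    adult = stages == "adult"
    ape_adult = adult & (groups == opt.ape_group)
    if ape_adult.sum() >= 3:
        group_fits["apes_adults"] = rma(ape_adult)
    for g in pd.unique(groups):
        if g == opt.ape_group:
            continue
        mask = adult & (groups == g)
        if mask.sum() >= 3:
            group_fits[str(g)] = rma(mask)

    # --- PLS-plane RMA and contrasts: apes vs hominins --------------------
    neuro1 = pls_model.scores[0]["dim1"].to_numpy()
    spl1 = pls_model.scores[1]["dim1"].to_numpy()
    is_ape = groups == opt.ape_group
    pls_fits: dict[str, allometry.RMAFit] = {}
    for name, mask in (("great_apes", is_ape), ("hominins", ~is_ape)):
        if mask.sum() >= 3:
            pls_fits[name] = rma(mask, x_label="pls_neuro1", y_label="pls_splanchno1",
                                 xs=neuro1, ys=spl1)
    slope_test = intercepts = None
    if len(pls_fits) == 2:
        a, b = pls_fits["great_apes"], pls_fits["hominins"]
        try:
            slope_test = allometry.clarke_test(a, b)
        except FitError:
            slope_test = None
        intercepts = allometry.compare_intercepts(a, b)

    # --- ontogenetic trajectory angles ------------------------------------
    extant_mask = np.isin(taxa, list(taxon_fits))
    angles = (
        allometry.centroid_angles(
            scores.to_numpy()[extant_mask], taxa[extant_mask], stages[extant_mask]
        )
        if extant_mask.any()
        else {}
    )

    # --- heterochrony decomposition against the reference trajectory ------
    decompositions: dict[str, heterochrony.TrajectoryDecomposition] = {}
    ref_mask = groups == opt.reference_group
    if ref_mask.sum() >= 3 and (stages[ref_mask] == "juvenile").any():
        ref_fit = rma(ref_mask)

        # the decomposition lives in the fit's (x=size, y=shape) plane
        def centroid_xy(mask):
            return np.array([f2[mask].mean(), f1[mask].mean()])

        juv_c = centroid_xy(ref_mask & (stages == "juvenile"))
        adu_c = centroid_xy(ref_mask & (stages == "adult"))
        polarity = heterochrony.ontogenetic_polarity(juv_c, adu_c, ref_fit)
        for g in pd.unique(groups):
            if g == opt.reference_group:
                continue
            mask = adult & (groups == g)
            if not mask.any():
                continue
            decompositions[str(g)] = heterochrony.decompose(
                ref_fit, polarity, centroid_xy(mask), deadband=opt.deadband
            )

    # --- encephalization associations --------------------------------------
    associations: dict[str, heterochrony.AssocResult] = {}
    partials: dict[str, heterochrony.PartialCorrelation] = {}
    geo_corr = None
    try:
        complete = subset_complete(ds)
    except ValidationError:
        complete = None
    if complete is not None and len(complete) >= 4:
        cf = complete.to_frame().set_index("specimen_id")
        enc = heterochrony.compute_eq(cf["bm_kg"], cf["ecv_cm3"], a=opt.eq_a, b=opt.eq_b)
        assoc_table = pd.DataFrame(
            {
                "factor1": scores.loc[cf.index, "factor1"],
                "factor2": scores.loc[cf.index, "factor2"],
                "logBM": enc.log_bm,
                "logECV": enc.log_ecv,
                "EQ": enc.eq,
                "group": cf["group"],
            },
            index=cf.index,
        )
        for g, sub in assoc_table.groupby("group", sort=False):
            sub = sub.drop(columns=["group"])
            if len(sub.dropna()) >= 4:
                associations[str(g)] = heterochrony.correlations(sub)
        homo = assoc_table[assoc_table["group"] == "extinct_Homo"]
        if len(homo) >= 5:
            partials["factor1_logECV_given_EQ"] = heterochrony.partial_correlation(
                homo["factor1"], homo["logECV"], homo["EQ"]
            )
            partials["factor1_EQ_given_logECV"] = heterochrony.partial_correlation(
                homo["factor1"], homo["EQ"], homo["logECV"]
            )
        homo_all = frame[(frame["group"] == "extinct_Homo") & frame["geo_age"].notna()]
        if len(homo_all) >= 4:
            from scipy import stats as _st

            r, p = _st.pearsonr(
                scores.loc[homo_all.index, "factor1"], homo_all["geo_age"].astype(float)
            )
            geo_corr = (float(r), float(p))

    # --- measurement-error robustness for fossil specimens -----------------
    robust_results: list[robustness.PerturbationResult] = []
    fossil_taxa = [t for t in pd.unique(taxa) if t not in taxon_fits]
    picked = [r for r in ds.records if r.taxon in fossil_taxa][: opt.n_robust_specimens]
    for i, rec in enumerate(picked):
        robust_results.append(
            robustness.perturb_and_project(
                rec, fmodel, error_level=opt.robust_error,
                n_reps=opt.robust_reps, seed=opt.seed + i,
            )
        )

    result = AnalysisResult(
        options=opt,
        pls_model=pls_model,
        factor_model=fmodel,
        isometry=iso,
        taxon_fits=taxon_fits,
        group_fits=group_fits,
        pls_fits=pls_fits,
        pls_slope_test=slope_test,
        pls_intercepts=intercepts,
        angles=angles,
        decompositions=decompositions,
        associations=associations,
        partials=partials,
        geo_age_correlation=geo_corr,
        robustness_results=robust_results,
    )
    result.tables = _build_tables(result)
    return result


def _build_tables(res: AnalysisResult) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}

    # integration summary mirroring the loadings/eigenvalue layout
    fm, pm = res.factor_model, res.pls_model
    summary = fm.loadings.copy()
    summary.insert(0, "pls_dim1", np.concatenate(
        [pm.loadings[0][:, 0], pm.loadings[1][:, 0]]
    )[[list(pm.variables).index(v) for v in fm.variables]])
    summary["h2"] = fm.communalities
    tables["loadings"] = summary
    tables["ordination_summary"] = pd.DataFrame(
        {
            "statistic": [
                "pls_singular_value_1", "pls_pct_covariation_1", "pls_score_correlation_1",
                "factor_eigenvalue_1", "factor_eigenvalue_2",
                "factor_pct_variance_1", "factor_pct_variance_2",
                "isometry_angle_to_factor1", "isometry_angle_to_factor2",
            ],
            "value": [
                pm.singular_values[0], pm.pct_covariation[0], pm.score_correlation[0],
                fm.eigenvalues[0], fm.eigenvalues[1],
                fm.pct_variance[0], fm.pct_variance[1],
                res.isometry.angle_to_factor1 if res.isometry else np.nan,
                res.isometry.angle_to_factor2 if res.isometry else np.nan,
            ],
        }
    )
    tables["factor_scores"] = fm.scores
    tables["pls_scores"] = pm.scores_table()
    tables["rma_taxa"] = allometry.rma_table(res.taxon_fits)
    tables["rma_groups"] = allometry.rma_table(res.group_fits)
    if res.pls_fits:
        tables["rma_pls_plane"] = allometry.rma_table(res.pls_fits)
    if res.angles:
        tables["centroid_angles"] = pd.DataFrame(
            [{"group": a.group, "angle_deg": a.angle_deg} for a in res.angles.values()]
        )
    if res.decompositions:
        tables["heterochrony_decomposition"] = pd.DataFrame(
            [
                {
                    "group": g,
                    "along": d.along,
                    "offset": d.offset,
                    "scaling_label": d.scaling_label,
                    "transposition_label": d.transposition_label,
                    "offset_threshold": d.offset_threshold,
                }
                for g, d in res.decompositions.items()
            ]
        )
    for g, assoc in res.associations.items():
        tables[f"correlations_{g}"] = assoc.correlation_matrix
        tables[f"correlation_pvalues_{g}"] = assoc.pvalues
    if res.partials:
        tables["partial_correlations"] = pd.DataFrame(
            [
                {"contrast": name, "r": p.r, "df": p.df, "p": p.p, "n": p.n}
                for name, p in res.partials.items()
            ]
        )
    if res.robustness_results:
        tables["robustness_summary"] = robustness.perturbation_summary(res.robustness_results)
    return tables


__all__ = ["AnalysisOptions", "AnalysisResult", "run_analysis"]
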