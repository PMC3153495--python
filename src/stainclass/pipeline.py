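"""End-to-end analysis driver.

``run_pipeline`` takes a configuration (a plain dict, JSON-serializable),
obtains a cohort (from a TSV path or by simulation), and produces one
report bundle containing, per target mutation and per scoring scheme: the
fitted logistic model, the ROC curve with AUC and DeLong CI, the
closest-to-corner cutoff, and diagnostic metrics in both rounding modes;
plus composite-target metrics (single-antibody calls OR-ed together),
paired DeLong comparisons of the best combined scheme against the
intensity-only readout, and — when outcome columns are present — response
rates with a chi-square/Fisher contrast, Kaplan-Meier medians with a
log-rank test, and a multivariate Cox model of PFS.

The report is reproducible: it embeds the seed, a digest of the
configuration and the package/library versions, and an overall content
hash (versions and environment excluded from the hash).
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from . import __version__
from .combine import (
    SeparationError,
    build_features,
    fit_logistic,
    predict_probability,
    schemes_for_target,
)
from .io import parse_genotype, read_cohort
from .metrics import (
    confusion_from_calls,
    diagnostic_metrics,
    expected_counts_below,
    fisher_exact,
    pearson_chi2,
)
from .roc import auc_confidence_interval, optimal_cutoff, paired_auc_test, roc_curve
from .simulate import SimConfig, simulate_cohort, simulate_outcomes
from .survival import cox_fit, km_estimate, logrank_test

logger = logging.getLogger("stainclass")

__all__ = ["run_pipeline", "PipelineError", "render_report"]

DEFAULT_TARGETS = ("L858R", "delE746-A750")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _metric_dict(ms):
    return {
        "sensitivity": ms.sensitivity,
        "specificity": ms.specificity,
        "ppv": ms.ppv,
        "npv": ms.npv,
        "accuracy": ms.accuracy,
        "lr_plus": ms.lr_plus,
        "lr_minus": ms.lr_minus,
        "undefined": list(ms.undefined),
        "infinite": list(ms.infinite),
    }


def _obtain_cohort(config):
    if config.get("cohort"):
        cohort, report = read_cohort(
            config["cohort"],
            tumor_content_min=config.get("tumor_content_min", 60.0),
        )
        source = {"kind": "file", "path": str(config["cohort"]),
                  "exclusions": vars(report)}
    else:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.setdefault("seed", config.get("seed", 0))
        sim = SimConfig(**sim_kwargs)
        cohort = simulate_cohort(sim)
        if config.get("outcomes", True):
            cohort = simulate_outcomes(cohort, sim)
        # route simulated data through the same validation gates as files
        keep = cohort["tumor_content"] >= config.get("tumor_content_min", 60.0)
        cohort = cohort[keep].reset_index(drop=True)
        source = {"kind": "simulated", "sim_seed": sim.seed,
                  "n_patients": len(cohort)}
    return cohort, source


def _scheme_row(cohort, scheme):
    X, y, names = build_features(cohort, scheme)
    if y.sum() == 0 or y.sum() == len(y):
        raise PipelineError(
            f"scheme {scheme.name!r}: cohort has a single truth class"
        )
    try:
        coefs = fit_logistic(X, y)
        separated = False
    except SeparationError:
        coefs = fit_logistic(X, y, firth=True)
        separated = True
        logger.warning("scheme %s: separated data, Firth fallback", scheme.name)
    scores = predict_probability(coefs, X)
    curve = roc_curve(scores, y)
    cut = optimal_cutoff(curve)
    _, ci_lo, ci_hi = auc_confidence_interval(scores, y)
    calls = (scores >= cut.threshold).astype(int)
    table = confusion_from_calls(calls, y)
    row = {
        "scheme": scheme.name,
        "target": scheme.target,
        "mutation_feature": scheme.mutation_feature,
        "total_egfr_feature": scheme.total_egfr_feature,
        "model": {
            "intercept": coefs.intercept,
            "slopes": dict(zip(names, coefs.slopes)),
            "converged": coefs.converged,
            "deviance": coefs.deviance,
            "method": coefs.method,
            "separation_fallback": separated,
        },
        "auc": curve.auc,
        "auc_ci_delong": [ci_lo, ci_hi],
        "cutoff": {
            "probability": cut.threshold,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
            "d2": cut.d2,
        },
        "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "metrics_exact": _metric_dict(diagnostic_metrics(table, "exact")),
        "metrics_printed": _metric_dict(diagnostic_metrics(table, "printed")),
    }
    return row, scores, calls, y


def _composite_rows(cohort, calls_by_target):
    """Table-4-style rows: per-antibody calls OR-ed against broader truths."""
    labels = [parse_genotype(g) for g in cohort["genotype"]]
    l_call = calls_by_target["L858R"]
    d_call = calls_by_target["delE746-A750"]
    truths = {
        "L858R": np.array([g.is_l858r for g in labels], int),
        "delE746-A750": np.array([g.is_e746_a750 for g in labels], int),
        "all Del-19": np.array([g.is_del19 for g in labels], int),
        "delE746-A750 or L858R": np.array(
            [g.is_e746_a750 or g.is_l858r for g in labels], int
        ),
        "Del-19 or L858R": np.array(
            [g.is_del19 or g.is_l858r for g in labels], int
        ),
    }
    calls = {
        "L858R": l_call,
        "delE746-A750": d_call,
        "all Del-19": d_call,
        "delE746-A750 or L858R": (l_call | d_call),
        "Del-19 or L858R": (l_call | d_call),
    }
    rows = []
    for name, truth in truths.items():
        table = confusion_from_calls(calls[name], truth)
        rows.append(
            {
                "genotype_target": name,
                "confusion": {
                    "tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn
                },
                "metrics_printed": _metric_dict(diagnostic_metrics(table, "printed")),
            }
        )
    return rows


def _encode_survival_frame(df):
    enc = pd.DataFrame(index=df.index)
    enc["male"] = (df["sex"] == "male").astype(float)
    enc["ever_smoker"] = (df["smoking"] == "ever").astype(float)
    enc["ecog_2_4"] = (df["ecog_ps"] == "2-4").astype(float)
    enc["ihc_positive"] = df["ihc_positive"].astype(float)
    enc["second_line_or_later"] = (df["treatment_line"] != "first").astype(float)
    enc["pfs_months"] = df["pfs_months"].astype(float)
    enc["pfs_event"] = df["pfs_event"].astype(float)
    return enc


def _outcome_stage(cohort):
    needed = {"tki_treated", "response", "pfs_months", "pfs_event", "ihc_positive"}
    if not needed.issubset(cohort.columns):
        return None
    tki = cohort[cohort["tki_treated"].fillna(0).astype(float) == 1].copy()
    tki = tki[np.isfinite(tki["pfs_months"].astype(float))]
    if len(tki) < 4 or tki["ihc_positive"].nunique() < 2:
        return None
    pos = tki[tki["ihc_positive"].astype(int) == 1]
    neg = tki[tki["ihc_positive"].astype(int) == 0]
    responder = tki["response"].isin(["CR", "PR"]).astype(int)
    table = [
        [int(responder[pos.index].sum()), int((1 - responder[pos.index]).sum())],
        [int(responder[neg.index].sum()), int((1 - responder[neg.index]).sum())],
    ]
    use_fisher = expected_counts_below(table)
    if use_fisher:
        p_resp = fisher_exact(table)
        test = "fisher"
    else:
        _, p_resp = pearson_chi2(table)
        test = "chi2"
    out = {
        "n_tki": len(tki),
        "response_rate_ihc_positive": 100.0 * table[0][0] / max(len(pos), 1),
        "response_rate_ihc_negative": 100.0 * table[1][0] / max(len(neg), 1),
        "response_table": table,
        "response_test": test,
        "response_p": p_resp,
    }
    try:
        km_pos = km_estimate(pos["pfs_months"], pos["pfs_event"].astype(int))
        km_neg = km_estimate(neg["pfs_months"], neg["pfs_event"].astype(int))
        chi2, p_lr = logrank_test(
            tki["pfs_months"], tki["pfs_event"].astype(int),
            tki["ihc_positive"].astype(int),
        )
        out["pfs"] = {
            "median_ihc_positive": km_pos.median,
            "median_ihc_negative": km_neg.median,
            "logrank_chi2": chi2,
            "logrank_p": p_lr,
        }
    except ValueError as exc:
        out["pfs"] = {"skipped": str(exc)}
    enc = _encode_survival_frame(tki)
    covariates = [
        c for c in ("male", "ever_smoker", "ecog_2_4", "ihc_positive",
                    "second_line_or_later")
        if enc[c].nunique() > 1
    ]
    try:
        cox = cox_fit(enc, covariates)
        out["cox"] = {
            cov: {
                "hr": float(cox.loc[cov, "hr"]),
                "ci": [float(cox.loc[cov, "hr_ci_low"]),
                       float(cox.loc[cov, "hr_ci_high"])],
                "p": float(cox.loc[cov, "p"]),
            }
            for cov in covariates
        }
    except Exception as exc:
        out["cox"] = {"skipped": str(exc)}
    return out


def run_pipeline(config: dict) -> dict:
    """Run the full scoring/ROC/metrics/outcome analysis from a config dict.

    Recognised keys: ``cohort`` (TSV path; if absent a cohort is simulated),
    ``simulate`` (SimConfig overrides), ``seed``, ``targets``,
    ``tumor_content_min``, ``outcomes`` (bool, simulate outcomes too).
    """
    cohort, source = _obtain_cohort(config)
    targets = list(config.get("targets", DEFAULT_TARGETS))

    scheme_rows = []
    calls_by_target = {}
    auc_comparisons = []
    for target in targets:
        per_scheme = {}
        for scheme in schemes_for_target(target):
            try:
                row, scores, calls, y = _scheme_row(cohort, scheme)
            except (PipelineError, SeparationError, ValueError) as exc:
                raise PipelineError(f"scoring stage [{scheme.name}]: {exc}") from exc
            scheme_rows.append(row)
            per_scheme[(scheme.mutation_feature, scheme.total_egfr_feature)] = (
                row, scores, calls, y
            )
        best_key = max(per_scheme, key=lambda k: per_scheme[k][0]["auc"])
        best_row, best_scores, best_calls, y = per_scheme[best_key]
        best_row["best_for_target"] = True
        calls_by_target[target] = best_calls
        intensity_scores = per_scheme[("intensity", "none")][1]
        cmp_res = paired_auc_test(best_scores, intensity_scores, y)
        auc_comparisons.append(
            {
                "target": target,
                "best_scheme": best_row["scheme"],
                "auc_best": cmp_res.auc_a,
                "auc_intensity_only": cmp_res.auc_b,
                "z": cmp_res.z,
                "p": cmp_res.p_value,
            }
        )

    composite = (
        _composite_rows(cohort, calls_by_target)
        if set(DEFAULT_TARGETS) <= set(targets)
        else []
    )

    outcome = _outcome_stage(cohort)
    if outcome is None:
        logger.info("outcome stage skipped: no usable outcome columns")

    results = {
        "n_patients": len(cohort),
        "schemes": scheme_rows,
        "auc_comparisons": auc_comparisons,
        "composite_targets": composite,
        "outcome": outcome,
        "outcome_skipped": outcome is None,
    }
    results = _jsonable(results)
    canonical = json.dumps(results, sort_keys=True)
    config_digest = hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    report = {
        "results": results,
        "meta": {
            "stainclass_version": __version__,
            "seed": config.get("seed", 0),
            "config_digest": config_digest,
            "source": _jsonable(source),
            "versions": _library_versions(),
        },
        "report_hash": hashlib.sha256(canonical.encode()).hexdigest(),
    }
    return report


def _library_versions():
    import lifelines
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "lifelines": lifelines.__version__,
    }


def render_report(report: dict) -> str:
    """Human-readable text rendering of a pipeline report."""
    r = report["results"]
    lines = [
        f"stainclass report (n = {r['n_patients']}, "
        f"seed = {report['meta']['seed']}, hash = {report['report_hash'][:12]})",
        "",
        f"{'scheme':<55}{'AUC':>7}{'sens%':>8}{'spec%':>8}{'PPV%':>7}"
        f"{'NPV%':>7}{'LR+':>8}{'LR-':>8}{'acc%':>7}",
    ]
    for row in r["schemes"]:
        m = row["metrics_printed"]
        star = "*" if row.get("best_for_target") else " "
        lr_plus = m["lr_plus"] if m["lr_plus"] is not None else "inf"
        lines.append(
            f"{row['scheme']+star:<55}{row['auc']:>7.3f}"
            f"{m['sensitivity']:>8.1f}{m['specificity']:>8.1f}{m['ppv']:>7.1f}"
            f"{m['npv']:>7.1f}{lr_plus!s:>8}{m['lr_minus']!s:>8}"
            f"{m['accuracy']:>7.1f}"
        )
    lines.append("")
    for cmp_row in r["auc_comparisons"]:
        lines.append(
            f"paired AUC ({cmp_row['target']}): best {cmp_row['auc_best']:.3f} vs "
            f"intensity-only {cmp_row['auc_intensity_only']:.3f}, "
            f"p = {cmp_row['p']:.3f}"
        )
    if r["composite_targets"]:
        lines.append("")
        lines.append("composite genotype targets (printed rounding):")
        for row in r["composite_targets"]:
            m = row["metrics_printed"]
            lines.append(
                f"  {row['genotype_target']:<28} sens {m['sensitivity']:.1f}% "
                f"spec {m['specificity']:.1f}% PPV {m['ppv']:.1f}% NPV {m['npv']:.1f}%"
            )
    if r["outcome"]:
        o = r["outcome"]
        lines.append("")
        lines.append(
            f"TKI outcomes (n = {o['n_tki']}): response "
            f"{o['response_rate_ihc_positive']:.1f}% (IHC+) vs "
            f"{o['response_rate_ihc_negative']:.1f}% (IHC-), "
            f"{o['response_test']} p = {o['response_p']:.3f}"
        )
        if "median_ihc_positive" in o.get("pfs", {}):
            p = o["pfs"]
            med_pos = p["median_ihc_positive"]
            med_neg = p["median_ihc_negative"]
            lines.append(
                f"  PFS medians {med_pos} vs {med_neg} months, "
                f"log-rank p = {p['logrank_p']:.3f}"
            )
    elif r["outcome_skipped"]:
        lines.append("")
        lines.append("outcome stage skipped (no usable outcome columns)")
    return "\n".join(lines)
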