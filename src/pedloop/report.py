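"""End-to-end pipeline: subset, decompose, assemble features, discriminate.

:func:`run_full_pipeline` chains the pedigree algebra and the canonical
discriminant analysis into a single deterministic report whose tables
mirror the shape of a herdbook diversity study: descriptive statistics of
the per-ancestor variables, multivariate test results, the leave-one-out
confusion matrix, Mahalanobis centroid distances and a dendrogram in
Newick form.  Conservation of every decomposition stage is checked and
logged into the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pedloop import __version__
from pedloop import cda as _cda
from pedloop.decompose import (
    founder_contributions,
    msv_decomposition_group,
    nca_contributions_group,
)
from pedloop.pedigree import Pedigree, subset_population
from pedloop.relationship import (
    compute_inbreeding,
    group_mean_coancestry,
    mendelian_sampling_variances,
    nonrandom_mating_alpha,
)

logger = logging.getLogger("pedloop")

DEFAULT_CONFIG = {
    "subset": "reference",  # historical | current | reference
    "group_level": "province",  # or municipality
    "vif_threshold": 5.0,
    "priors": "proportional",
    "linkage": "upgma",
    "min_group_size": 2,
    "conservation_tol": 1e-8,
}

EXPORT_FILES = [
    "descriptives.csv",
    "tests.json",
    "confusion.csv",
    "distances.csv",
    "dendrogram.nwk",
    "summary.txt",
]


@dataclass
class PipelineReport:
    """Everything :func:`run_full_pipeline` computes, plus provenance."""

    pedigree_summary: dict
    conservation: dict
    descriptives: pd.DataFrame
    feature_table: pd.DataFrame
    vif_report: list
    cda_summary: dict | None
    tests: dict | None
    classification: _cda.ClassificationReport | None
    distances: pd.DataFrame | None
    newick: str | None
    notices: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def cda_skipped(self) -> bool:
        return self.tests is None


def _resolve_subset(pedigree: Pedigree, name: str):
    if name == "historical":
        return subset_population(pedigree, "historical")
    if name == "current":
        return subset_population(pedigree, "current", alive=True)
    if name == "reference":
        return subset_population(pedigree, "reference", both_parents_known=True)
    raise ValueError(f"unknown subset {name!r}")


def run_full_pipeline(pedigree: Pedigree, config: dict | None = None) -> PipelineReport:
    """Run subsetting, decomposition, feature assembly and CDA.

    Deterministic given the pedigree and configuration.  When no inbred
    animal exists (no loop ever closes) the CDA stages are skipped with an
    explanatory notice and the report still carries the descriptive part.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    notices: list[str] = []
    tol = float(cfg["conservation_tol"])

    F = compute_inbreeding(pedigree)
    b = mendelian_sampling_variances(pedigree, F)
    subset = _resolve_subset(pedigree, cfg["subset"])
    members = sorted(subset.member_ids)
    if not members:
        raise ValueError(f"subset {cfg['subset']!r} selected no animals")
    positions = [pedigree.position(a) for a in members]
    mean_f_direct = float(np.mean(F[positions]))
    coan = group_mean_coancestry(pedigree, members, b=b)
    alpha = nonrandom_mating_alpha(mean_f_direct, coan.coancestry)

    # decomposition: MSV -> NCA -> founders, for both group targets
    m_meanF = msv_decomposition_group(pedigree, b, members, target="mean_F")
    m_meanC = msv_decomposition_group(pedigree, b, members, target="mean_coancestry")
    u_meanF = nca_contributions_group(pedigree, members, target="mean_F", F=F)
    u_meanC = nca_contributions_group(pedigree, members, target="mean_coancestry", F=F)
    v_meanF = founder_contributions(pedigree, u_meanF)
    v_meanC = founder_contributions(pedigree, u_meanC)

    conservation = {
        "mean_F_direct": mean_f_direct,
        "mean_coancestry_direct": coan.coancestry,
        "alpha": alpha,
        "residual_m_meanF": abs(m_meanF.total - mean_f_direct),
        "residual_u_meanF": abs(u_meanF.total - mean_f_direct),
        "residual_v_meanF": abs(v_meanF.total - mean_f_direct),
        "residual_m_meanC": abs(m_meanC.total - coan.coancestry),
        "residual_u_meanC": abs(u_meanC.total - coan.coancestry),
        "residual_v_meanC": abs(v_meanC.total - coan.coancestry),
    }
    for key, value in conservation.items():
        if key.startswith("residual"):
            logger.info("conservation %s: max abs residual %.3e", key, value)
            if value > tol:
                notices.append(f"conservation residual {key} = {value:.3e} exceeds {tol}")

    features = _cda.assemble_ancestor_features(pedigree, u_meanC, v_meanF, v_meanC)
    descriptives = _describe(features)

    summary = {
        "n_animals": len(pedigree),
        "n_subset": len(members),
        "subset": cfg["subset"],
        "n_founders": len(pedigree.founders()),
        "n_inbred": int(np.sum(F > 0)),
        "mean_F": mean_f_direct,
        "mean_coancestry": coan.coancestry,
        "alpha": alpha,
    }
    provenance = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
    }

    if features.empty or summary["n_inbred"] == 0:
        notices.append(
            "no inbreeding loops in the subset: decomposition is empty and the "
            "discriminant analysis was skipped"
        )
        return PipelineReport(
            pedigree_summary=summary,
            conservation=conservation,
            descriptives=descriptives,
            feature_table=features,
            vif_report=[],
            cda_summary=None,
            tests=None,
            classification=None,
            distances=None,
            newick=None,
            notices=notices,
            provenance=provenance,
        )

    group_col = cfg["group_level"]
    labeled = features.dropna(subset=[group_col])
    counts = labeled[group_col].value_counts()
    valid_groups = counts[counts >= int(cfg["min_group_size"])].index
    dropped = sorted(set(counts.index) - set(valid_groups))
    if dropped:
        notices.append(f"groups below minimum size excluded from CDA: {dropped}")
    labeled = labeled[labeled[group_col].isin(valid_groups)]
    if labeled.empty or labeled[group_col].nunique() < 2:
        notices.append("fewer than two usable origin groups; CDA skipped")
        return PipelineReport(
            pedigree_summary=summary,
            conservation=conservation,
            descriptives=descriptives,
            feature_table=features,
            vif_report=[],
            cda_summary=None,
            tests=None,
            classification=None,
            distances=None,
            newick=None,
            notices=notices,
            provenance=provenance,
        )

    numeric = labeled[_cda.FEATURE_COLUMNS]
    screened, vif_report = _cda.collinearity_screen(
        numeric, threshold=float(cfg["vif_threshold"])
    )
    y = labeled[group_col]
    model = _cda.fit_canonical_discriminant(screened, y)
    tests = _cda.discriminant_significance_tests(
        model.eigenvalues, n=model.n, p=model.p, g=model.g
    )
    tests["univariate"] = (
        _cda.univariate_equality_tests(screened[model.variables], y)
        .reset_index()
        .to_dict(orient="records")
    )
    classification = _cda.loocv_classification(
        screened[model.variables], y, priors=cfg["priors"]
    )
    distances = _cda.mahalanobis_centroid_distances(screened[model.variables], y)
    _, newick = _cda.distance_dendrogram(distances, linkage=cfg["linkage"])
    cda_summary = {
        "variables": model.variables,
        "groups": [str(gp) for gp in model.groups],
        "eigenvalues": model.eigenvalues.tolist(),
        "percent_discrimination": model.percent_discrimination.tolist(),
        "canonical_correlations": model.canonical_correlations.tolist(),
        "notices": model.notices,
    }
    notices.extend(model.notices)
    return PipelineReport(
        pedigree_summary=summary,
        conservation=conservation,
        descriptives=descriptives,
        feature_table=features,
        vif_report=vif_report,
        cda_summary=cda_summary,
        tests=tests,
        classification=classification,
        distances=distances,
        newick=newick,
        notices=notices,
        provenance=provenance,
    )


def _describe(features: pd.DataFrame) -> pd.DataFrame:
    """Mean, min, max and SD of each analysis variable."""
    numeric = features[[c for c in _cda.FEATURE_COLUMNS if c in features.columns]]
    if numeric.empty:
        return pd.DataFrame(columns=["mean", "min", "max", "sd"])
    return pd.DataFrame(
        {
            "mean": numeric.mean(),
            "min": numeric.min(),
            "max": numeric.max(),
            "sd": numeric.std(ddof=1),
        }
    )


def _fmt_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda v: float(f"{v:.6g}") if isinstance(v, (int, float, np.floating)) else v)


def export_report(report: PipelineReport, out_dir) -> list[str]:
    """Write the six report files and return their paths.

    Floats are serialized at six significant digits so re-exports are
    byte-identical.  A skipped CDA is marked explicitly in ``tests.json``
    and the dependent files are written empty.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _path(name: str) -> Path:
        written.append(str(out / name))
        return out / name

    _fmt_frame(report.descriptives).to_csv(_path("descriptives.csv"))

    payload: dict = {"provenance": report.provenance, "notices": report.notices}
    if report.cda_skipped:
        payload["cda"] = "skipped"
    else:
        payload["cda"] = report.cda_summary
        payload["tests"] = json.loads(
            json.dumps(report.tests, default=lambda v: float(f"{v:.6g}"))
        )
        payload["classification"] = {
            "overall_hit_ratio": float(f"{report.classification.overall_hit:.6g}"),
            "per_group_hit_ratio": {
                str(k): float(f"{v:.6g}")
                for k, v in report.classification.per_group_hit.items()
            },
            "press_q": float(f"{report.classification.press_q:.6g}"),
            "press_q_critical": report.classification.press_q_critical,
            "proportional_chance": float(
                f"{report.classification.proportional_chance:.6g}"
            ),
            "max_chance": float(f"{report.classification.max_chance:.6g}"),
            "beats_chance_125": bool(report.classification.beats_chance_125),
        }
    payload["conservation"] = {
        k: float(f"{v:.6g}") for k, v in report.conservation.items()
    }
    payload["pedigree"] = {
        k: (float(f"{v:.6g}") if isinstance(v, float) else v)
        for k, v in report.pedigree_summary.items()
    }
    with open(_path("tests.json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if report.classification is not None:
        report.classification.confusion.to_csv(_path("confusion.csv"))
    else:
        _path("confusion.csv").write_text("")
    if report.distances is not None:
        _fmt_frame(report.distances).to_csv(_path("distances.csv"))
    else:
        _path("distances.csv").write_text("")
    _path("dendrogram.nwk").write_text((report.newick or "") + "\n")

    lines = [
        f"pedloop {report.provenance.get('version', '?')} pipeline summary",
        "",
        "Pedigree: "
        + ", ".join(f"{k}={_fmt(v)}" for k, v in report.pedigree_summary.items()),
        "Conservation residuals: "
        + ", ".join(
            f"{k.removeprefix('residual_')}={v:.3e}"
            for k, v in report.conservation.items()
            if k.startswith("residual")
        ),
    ]
    if report.cda_skipped:
        lines.append("CDA: skipped")
    else:
        lam = ", ".join(f"{v:.6g}" for v in report.cda_summary["eigenvalues"])
        lines.append(f"CDA eigenvalues: {lam}")
        lines.append(
            f"Wilks lambda: {report.tests['wilks']['lambda']:.6g} "
            f"(p={report.tests['wilks']['p_value']:.4g}); "
            f"Pillai V: {report.tests['pillai']['V']:.6g} "
            f"(p={report.tests['pillai']['p_value']:.4g})"
        )
        lines.append(
            f"LOOCV hit ratio: {report.classification.overall_hit:.6g}; "
            f"Press's Q: {report.classification.press_q:.6g}"
        )
    if report.notices:
        lines.append("Notices:")
        lines.extend(f"  - {n}" for n in report.notices)
    _path("summary.txt").write_text("\n".join(lines) + "\n")
    return written


def _fmt(v):
    return f"{v:.6g}" if isinstance(v, float) else v
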