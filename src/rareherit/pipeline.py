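"""End-to-end pipeline: simulate -> QC -> duo validation -> GRMs -> REML -> prediction.

Writes every intermediate artifact (VCF, TSV tables, GRM text files) plus a
machine-readable ``report.json`` holding the variance tables, the
likelihood-ratio table, the duo-validation summaries and the prediction
metrics.  The same seed and configuration produce a byte-identical report;
timings go to a separate run log so they never perturb the report.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import io
from .config import RunConfig, save_config
from .datatypes import RelationshipMatrix
from .duos import (
    duo_reference_maf,
    estimate_error_fraction,
    fit_quadratic,
    fit_saturation,
    make_maf_bins,
    observed_transmission,
    pooled_transmission,
    saturation_resample,
    validate_rare_variants,
)
from .greml import VarianceModel, loglik_ratio_test, missing_heritability, reml_fit
from .prediction import evaluate, gblup_predict, split_train_validation
from .qc import QCThresholds, classify_maf, filter_sites, prune_ld, proximity_filter, qc_report
from .relationships import build_grm, build_nrm, write_grm_text
from .simulate import (
    assign_effects_and_phenotypes,
    inject_sequencing_errors,
    simulate_genotypes,
    simulate_pedigree,
    unrelated_pairs,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, artifacts: list[str], cause: Exception):
        super().__init__(
            f"pipeline stage {stage!r} failed ({cause}); artifacts written so far: "
            f"{', '.join(artifacts) or 'none'}"
        )
        self.stage = stage
        self.artifacts = artifacts


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic population; returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    timings: dict[str, float] = {}
    report: dict = {"seed": config.seed}
    stage = "setup"

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts.append(str(path))

    try:
        # ---- simulate -------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        sim = config.sim
        ped = simulate_pedigree(sim)
        vt_clean = simulate_genotypes(ped, sim)
        phen, truth, vt_visible = assign_effects_and_phenotypes(vt_clean, ped, sim)
        vt = inject_sequencing_errors(vt_visible, sim)
        _write("genotypes.vcf", lambda p: io.write_vcf(vt, p))
        _write("pedigree.tsv", lambda p: io.write_pedigree(ped, p))
        _write("phenotypes.tsv", lambda p: io.write_phenotypes(phen, p))
        _write("duos.tsv", lambda p: io.write_duos(ped.duos, p))
        _write("config.yaml", lambda p: save_config(config, p))
        report["simulate"] = {
            "n_animals": len(ped.ids),
            "n_duos": len(ped.duos),
            "n_sites": vt.n_sites,
            "true_variances": {k: _round(v) for k, v in truth["variances"].items()},
            "sigma_e2": _round(truth["sigma_e2"]),
        }
        timings[stage] = time.perf_counter() - t0

        # ---- QC -------------------------------------------------------
        stage = "qc"
        t0 = time.perf_counter()
        th = QCThresholds(**config.qc)
        vt_f, counts = filter_sites(vt, ped.duos, th)
        vt_f = proximity_filter(vt_f, th)
        vt_p, n_zero_var = prune_ld(vt_f, th)
        classing = classify_maf(vt_p, th)
        _write("qc_report.tsv", lambda p: qc_report(counts).to_csv(p, sep="\t", index=False))
        _write("genotypes_qc.vcf", lambda p: io.write_vcf(vt_p, p))
        report["qc"] = {
            "removal_counts": counts,
            "zero_variance_warnings": n_zero_var,
            "n_sites_after": vt_p.n_sites,
            "class_counts": classing["maf_class"].value_counts().sort_index().to_dict(),
        }
        timings[stage] = time.perf_counter() - t0

        # ---- duo validation ------------------------------------------
        stage = "duo_validation"
        t0 = time.perf_counter()
        dopt = config.duo
        maf = duo_reference_maf(vt_p, ped.duos)
        bins = make_maf_bins(maf, n_bins=int(dopt.get("n_bins", 25)))
        per_duo = observed_transmission(vt_p, ped.duos, bins, maf=maf)
        pooled = pooled_transmission(per_duo)
        pooled["expected"] = 0.5 + 0.5 * pooled["mean_maf"]
        pooled["error_fraction"] = estimate_error_fraction(
            pooled["proportion"].to_numpy(), pooled["mean_maf"].to_numpy()
        )
        _write("transmission.tsv", lambda p: pooled.to_csv(p, sep="\t", index=False))
        validated = validate_rare_variants(
            vt_p, ped.duos, th, strict_het=bool(dopt.get("strict_het", False))
        )
        _write("validated_rare_variants.tsv",
               lambda p: validated.to_csv(p, sep="\t", index=False))
        sat = saturation_resample(
            vt_p, ped.duos,
            n_replicates=int(dopt.get("n_replicates", 50)),
            seed=config.seed,
            thresholds=th,
            strict_het=bool(dopt.get("strict_het", False)),
        )
        _write("saturation.tsv", lambda p: sat.to_csv(p, sep="\t", index=False))
        quad = fit_quadratic(sat)
        try:
            satfit = fit_saturation(sat)
            sat_params = {"T": _round(satfit.T), "k": _round(satfit.k)}
        except (RuntimeError, ValueError) as err:
            sat_params = {"error": str(err)}
        report["duo_validation"] = {
            "n_validated_rare": len(validated),
            "rare_bin_error_fraction": _round(
                float(pooled["error_fraction"].iloc[0]) if len(pooled) else np.nan
            ),
            "quadratic": {
                "a": _round(quad.a), "b": _round(quad.b), "c": _round(quad.c),
                "duos_needed": quad.duos_needed,
                "projected_max": _round(quad.projected_max)
                if quad.projected_max is not None else None,
            },
            "saturation": sat_params,
        }
        timings[stage] = time.perf_counter() - t0

        # ---- relationship matrices -----------------------------------
        stage = "relationships"
        t0 = time.perf_counter()
        nrm = build_nrm(ped)
        grms: dict[str, RelationshipMatrix] = {}
        for label in ("common", "uncommon", "rare"):
            mask = (classing["maf_class"] == label).to_numpy()
            if mask.sum() >= 2:
                grms[label] = build_grm(vt_p.take_sites(mask), source=label)
        for label, rm in grms.items():
            write_grm_text(rm, str(out / f"grm_{label}"))
            artifacts.append(str(out / f"grm_{label}.grm.txt"))
        report["relationships"] = {
            "n_markers": {k: rm.n_markers for k, rm in grms.items()},
            "mean_diag": {k: _round(float(np.mean(np.diag(rm.matrix))))
                          for k, rm in grms.items()},
        }
        timings[stage] = time.perf_counter() - t0

        # ---- REML variance partitioning ------------------------------
        stage = "greml"
        t0 = time.perf_counter()
        fit_ped = reml_fit(phen, VarianceModel(components=[("pedigree", nrm)]))
        fit_common = reml_fit(phen, VarianceModel(components=[("common", grms["common"])]))
        sigma_a2 = fit_ped.sigma2["pedigree"]
        sigma_g2 = fit_common.sigma2["common"]
        separate_fits = {
            "pedigree": {"sigma_a2": _round(sigma_a2), "se": _round(fit_ped.se["pedigree"])},
            "common_markers": {"sigma_g2": _round(sigma_g2),
                               "se": _round(fit_common.se["common"])},
            "missing_heritability_pct": _round(100.0 * missing_heritability(sigma_a2, sigma_g2), 2)
            if sigma_a2 > 0 else None,
        }

        joint_components = [("pedigree", nrm)] + [(lab, grms[lab]) for lab in
                                                  ("common", "uncommon", "rare")
                                                  if lab in grms]
        fit_joint = reml_fit(phen, VarianceModel(components=joint_components))
        joint_partition = {
            "proportions_pct": {k: _round(v, 2) for k, v in fit_joint.proportions.items()},
            "total_additive_variance": _round(
                sum(v for k, v in fit_joint.sigma2.items() if k != "residual")
            ),
            "converged": fit_joint.converged,
        }

        lrt_table = {}
        for label in ("pedigree", "rare", "uncommon"):
            if label != "pedigree" and label not in grms:
                continue
            extra = nrm if label == "pedigree" else grms[label]
            alt = reml_fit(
                phen,
                VarianceModel(components=[("common", grms["common"]), (label, extra)]),
            )
            stat, sig = loglik_ratio_test(fit_common, alt)
            lrt_table[f"common_plus_{label}"] = {
                "lrt": _round(stat, 4), "significant_p0.005": bool(sig),
            }
        report["variance_tables"] = {
            "separate_fits": separate_fits,
            "lrt": lrt_table,
            "joint_partition": joint_partition,
        }
        timings[stage] = time.perf_counter() - t0

        # ---- prediction ----------------------------------------------
        stage = "prediction"
        t0 = time.perf_counter()
        frac = float(config.prediction.get("validation_fraction", 0.15))
        n_val = max(3, int(round(frac * len(phen.ids))))
        train_ids, val_ids = split_train_validation(ped, phen, n_val)
        phen_train = phen.subset(train_ids)
        observed = phen.subset(val_ids).values
        sigma_a2_train = reml_fit(
            phen_train, VarianceModel(components=[("pedigree", nrm)])
        ).sigma2["pedigree"]
        scale = sigma_a2_train if sigma_a2_train > 0 else float(np.var(phen_train.values))

        pred_models = {"pedigree_blup": [("pedigree", nrm)]}
        if "common" in grms:
            pred_models["gblup_common"] = [("common", grms["common"]), ("polygenic", nrm)]
        if "common" in grms and "rare" in grms:
            pred_models["gblup_common_rare"] = [
                ("common", grms["common"]), ("rare", grms["rare"]), ("polygenic", nrm),
            ]
        metrics = {}
        for name, comps in pred_models.items():
            pred = gblup_predict(phen_train, VarianceModel(components=comps), val_ids)
            res = evaluate(pred, observed, scale)
            metrics[name] = {
                "cor": _round(res.cor, 4),
                "slope": _round(res.slope, 4),
                "mse": _round(res.mse_sd, 4),
            }
        report["prediction"] = {
            "n_train": len(train_ids),
            "n_validation": len(val_ids),
            "metrics": metrics,
            "mse_scale": "variance",
        }
        timings[stage] = time.perf_counter() - t0

        # ---- report ---------------------------------------------------
        stage = "report"
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts.append(str(report_path))
        with open(out / "run.log", "w") as fh:
            fh.write(f"seed: {config.seed}\n")
            for name, dt in timings.items():
                fh.write(f"{name}: {dt:.3f}s\n")
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - surfaced with stage context
        raise PipelineError(stage, artifacts, err) from err
    return report
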