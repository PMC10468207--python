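"""Reproducible multi-stage synthetic pipeline.

A single YAML-serializable configuration (one seed, per-stage parameters)
drives synthetic data generation and every downstream analysis stage, and
a JSON run report records the resolved value of every parameter, per-stage
results, and exact record bookkeeping (inputs = outputs + excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from . import imaging, io, kinetics, masspt, synth, xlms

logger = logging.getLogger(__name__)

ALL_STAGES = ("synth", "kinetics", "xlms", "masspt", "imaging")

try:
    _VERSION = version("ihp")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


@dataclass
class RunConfig:
    """Pipeline configuration; one seed governs every stochastic stage."""

    seed: int = 0
    outdir: str = "ihp_out"
    stages: tuple[str, ...] = ALL_STAGES
    # kinetics truth/fit settings
    kinetic_a1: float = 0.6
    kinetic_r1: float = 0.3
    kinetic_k2: float = 0.004
    noise_sd: float = 0.05
    saturating: tuple[float, ...] = (100.0,)
    # crosslink settings
    xl_n_crosslinks: int = 200
    xl_hetero_ratio: float = 0.25
    xl_noise_cv: float = 0.2
    r_denominator: str = "homotypic_sum"
    hetero_floor: float = 0.0
    # mass photometry settings
    mass_n_events: int = 10_000
    monomer_kda: float = 55.0
    ligand_kda: float = masspt.CALMODULIN_KDA
    ligand_count: int = 1
    oligomer_candidates: tuple[int, ...] = (2, 4, 12, 24)
    # imaging settings
    coloc_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    coloc_replicates: int = 5
    top_fraction: float = 0.01
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "saturating", "oligomer_candidates", "coloc_fractions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write tables plus a JSON report.

    Deterministic given an identical configuration; on a stage failure the
    report records partial results and the failing stage, and the error is
    re-raised after the report is written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(ALL_STAGES, _derive_seeds(config.seed, len(ALL_STAGES))))
    report: dict = {
        "version": _VERSION,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "derived_seeds": seeds,
        "stages": {},
    }
    datasets: dict = {}
    stage = None
    try:
        for stage in config.stages:
            report["stages"][stage] = _STAGE_RUNNERS[stage](config, seeds[stage],
                                                           outdir, datasets)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        io.write_json_report(report, outdir / "report.json")
        raise
    io.write_json_report(report, outdir / "report.json")
    return report


def _truth(config: RunConfig, seed: int) -> synth.KineticTruth:
    return synth.KineticTruth(a1=config.kinetic_a1, r1=config.kinetic_r1,
                              k2=config.kinetic_k2, noise_sd=config.noise_sd,
                              seed=seed)


def _run_synth(config, seed, outdir, datasets):
    sub = _derive_seeds(seed, 3 + len(synth.XL_SCENARIOS))
    datasets["timecourse"] = synth.gen_timecourse(_truth(config, sub[0]))
    io.write_timecourse(datasets["timecourse"], outdir / "timecourse.tsv")
    datasets["xl"] = {}
    for i, name in enumerate(synth.XL_SCENARIOS):
        scn = synth.XlScenario(name=name, n_crosslinks=config.xl_n_crosslinks,
                               hetero_ratio=config.xl_hetero_ratio,
                               noise_cv=config.xl_noise_cv, seed=sub[1 + i])
        datasets["xl"][name] = synth.gen_xl_table(scn)
        io.write_xl_table(datasets["xl"][name], outdir / f"xl_{name}.tsv")
    mass_truth = synth.MassMixtureTruth(n_events=config.mass_n_events, seed=sub[-2])
    datasets["mass"] = synth.gen_mass_events(mass_truth, condition="activated")
    io.write_mass_events(datasets["mass"], outdir / "mass_events.csv")
    datasets["mass_truth"] = mass_truth
    img_seeds = _derive_seeds(sub[-1], len(config.coloc_fractions) * config.coloc_replicates)
    datasets["images"] = {}
    k = 0
    for frac in config.coloc_fractions:
        for rep in range(config.coloc_replicates):
            truth = synth.SpotImageTruth(coloc_fraction=frac, seed=img_seeds[k])
            datasets["images"][(frac, rep)] = synth.gen_spot_images(truth)
            k += 1
    return {
        "timecourse_rows": len(datasets["timecourse"]),
        "xl_rows": {n: len(t) for n, t in datasets["xl"].items()},
        "mass_events": len(datasets["mass"].masses),
        "image_pairs": len(datasets["images"]),
    }


def _run_kinetics(config, seed, outdir, datasets):
    table = datasets.get("timecourse")
    if table is None:
        table = synth.gen_timecourse(_truth(config, _derive_seeds(seed, 1)[0]))
    fit = kinetics.fit_global(table, saturating=set(config.saturating))
    truth = {"a1": config.kinetic_a1, "r1": config.kinetic_r1, "k2": config.kinetic_k2}
    result = {
        "fit": {"a1": fit.a1, "r1": fit.r1, "k2": fit.k2,
                "weighted_ssr": fit.weighted_ssr,
                "half_times_min": {str(c): t for c, t in fit.half_times.items()},
                "single_component": {str(c): f for c, f in fit.single_component.items()}},
        "truth": truth,
        "relative_error": {k: abs(getattr(fit, k) - v) / v for k, v in truth.items()},
        "n_rows_in": len(table),
        "n_rows_used": fit.n_points,
        "n_rows_excluded": 0,
    }
    io.write_json_report(result, outdir / "kinetics_fit.json")
    return result


def _run_xlms(config, seed, outdir, datasets):
    tables = datasets.get("xl")
    if tables is None:
        sub = _derive_seeds(seed, len(synth.XL_SCENARIOS))
        tables = {
            name: synth.gen_xl_table(
                synth.XlScenario(name=name, n_crosslinks=config.xl_n_crosslinks,
                                 hetero_ratio=config.xl_hetero_ratio,
                                 noise_cv=config.xl_noise_cv, seed=s)
            )
            for name, s in zip(synth.XL_SCENARIOS, sub)
        }
    out = {}
    for name, table in tables.items():
        quant = xlms.quantify(table, denominator=config.r_denominator,
                              hetero_floor=config.hetero_floor)
        summary = xlms.summarize_ratios(quant)
        heat_het = xlms.build_heatmap(table, mode="heterotypic",
                                      hetero_floor=config.hetero_floor)
        heat_hom = xlms.build_heatmap(table, mode="homotypic",
                                      hetero_floor=config.hetero_floor)
        summary.to_csv(outdir / f"xl_{name}_ratios.tsv", sep="\t", index=False)
        heat_het.to_csv(outdir / f"xl_{name}_heatmap_heterotypic.tsv", sep="\t")
        heat_hom.to_csv(outdir / f"xl_{name}_heatmap_homotypic.tsv", sep="\t")
        n_undef = int((~quant["R_defined"]).sum())
        out[name] = {
            "n_records_in": len(table),
            "n_R_defined": int(quant["R_defined"].sum()),
            "n_R_undefined": n_undef,
            "heterotypic_counts": heat_het.to_dict(),
            "homotypic_counts": heat_hom.to_dict(),
            "mean_R_by_domain_pair": {
                row["domain_pair"]: row["mean_R"] for _, row in summary.iterrows()
            },
        }
    return out


def _run_masspt(config, seed, outdir, datasets):
    events = datasets.get("mass")
    if events is None:
        events = synth.gen_mass_events(
            synth.MassMixtureTruth(n_events=config.mass_n_events,
                                   seed=_derive_seeds(seed, 1)[0]),
            condition="activated",
        )
    fit = masspt.fit_mixture(events)
    peaks = masspt.annotate_peaks(fit, monomer_mass=config.monomer_kda,
                                  candidates=config.oligomer_candidates,
                                  ligand_mass=config.ligand_kda,
                                  ligand_count=config.ligand_count)
    result = {
        "n_events_in": len(events.masses),
        "n_events_used": len(events.masses),
        "peaks": [
            {"mean_kDa": pk.mean, "sd_kDa": pk.sd, "area_pct": pk.area_pct,
             "n_mer": pk.n_mer, "monomer_pct": pk.monomer_pct}
            for pk in peaks
        ],
    }
    io.write_json_report(result, outdir / "masspt_fit.json")
    return result


def _run_imaging(config, seed, outdir, datasets):
    images = datasets.get("images")
    if images is None:
        img_seeds = _derive_seeds(seed, len(config.coloc_fractions) * config.coloc_replicates)
        images = {}
        k = 0
        for frac in config.coloc_fractions:
            for rep in range(config.coloc_replicates):
                images[(frac, rep)] = synth.gen_spot_images(
                    synth.SpotImageTruth(coloc_fraction=frac, seed=img_seeds[k])
                )
                k += 1
    groups: dict[str, list[float]] = {}
    for (frac, rep), pair in images.items():
        res = imaging.pearson_coloc(pair, top_fraction=config.top_fraction,
                                    condition=f"coloc_{frac}", replicate=rep)
        groups.setdefault(res.condition, []).append(res.pearson_r)
    control = f"coloc_{min(f for f, _ in images)}"
    comparisons = imaging.compare_to_control(
        groups, control=control, alpha=config.alpha,
        random_state=np.random.default_rng(seed),
    )
    comparisons.to_csv(outdir / "coloc_comparisons.tsv", sep="\t", index=False)
    return {
        "n_pairs_in": len(images),
        "n_pairs_scored": sum(len(v) for v in groups.values()),
        "mean_pearson_by_condition": {k: float(np.mean(v)) for k, v in groups.items()},
        "control": control,
        "comparisons": comparisons.to_dict(orient="records"),
    }


_STAGE_RUNNERS = {
    "synth": _run_synth,
    "kinetics": _run_kinetics,
    "xlms": _run_xlms,
    "masspt": _run_masspt,
    "imaging": _run_imaging,
}
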