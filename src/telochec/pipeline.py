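"""End-to-end driver: simulate -> render -> call -> consolidate -> interpret.

``analyze_template`` runs the whole inference chain for one template and is
the unit every higher-level entry point (CLI, acceptance checks, fold-back
report) composes.  All randomness flows from a single master seed; per-lane
streams are derived from it by hashing the lane identity, so any subset of
lanes reproduces identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import caller, chec_sim, gel, inference, io, templates

DEFAULT_CONSTRUCTS = ("GBD-MN", "NLS-MN", "MN-Rap1", "H2A-MN")


@dataclass(frozen=True)
class RunConfig:
    templates: tuple[str, ...] = ("YpTRF", "TEL03L", "TEL06R", "X05R_AF", "X16R_AF")
    constructs: tuple[str, ...] = DEFAULT_CONSTRUCTS
    genotype: str = "WT"
    n_molecules: int = 2000
    base_rate: float = 0.04
    seed: int = 0
    tolerance: float = caller.DEFAULT_CLUSTER_TOLERANCE
    min_prominence: float = caller.DEFAULT_MIN_PROMINENCE
    h2a_cold_prominence: float = caller.H2A_COLD_PROMINENCE
    classifier_threshold: float = inference.NUCLEOSOME_THRESHOLD
    ladder_noise: float = 0.0
    schedule: tuple = chec_sim.DEFAULT_SCHEDULE
    outdir: str | None = None

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        cfg = io.read_config(path)
        cfg.update(overrides)
        if "templates" in cfg and isinstance(cfg["templates"], str):
            cfg["templates"] = (cfg["templates"],)
        if "constructs" in cfg and isinstance(cfg["constructs"], str):
            cfg["constructs"] = (cfg["constructs"],)
        return cls(**cfg)

    def digest(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "outdir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TemplateResult:
    template: templates.SubtelomereTemplate
    populations: list
    lane_bands: dict
    sites: list
    intervals: list
    model: inference.ChromatinModel
    ratios: dict
    calibration: gel.GelCalibration


@dataclass
class PipelineResult:
    config: RunConfig
    results: dict  # template name -> TemplateResult
    foldback: dict = field(default_factory=dict)


def exclusion_size(template: templates.SubtelomereTemplate) -> float:
    """Size above which a band is treated as the uncut/full-length signal."""
    if template.terminal:
        return template.core_length + 10.0
    return 0.97 * template.length


def analyze_template(
    name: str,
    seed: int,
    n_molecules: int = 2000,
    constructs=DEFAULT_CONSTRUCTS,
    genotype: str = "WT",
    variant: str = "",
    base_rate: float = 0.04,
    schedule=chec_sim.DEFAULT_SCHEDULE,
    tolerance: float = caller.DEFAULT_CLUSTER_TOLERANCE,
    min_prominence: float = caller.DEFAULT_MIN_PROMINENCE,
    h2a_cold_prominence: float = caller.H2A_COLD_PROMINENCE,
    classifier_threshold: float = inference.NUCLEOSOME_THRESHOLD,
    ladder_noise: float = 0.0,
    min_site_support: int = 2,
) -> TemplateResult:
    """Full simulate/render/call/consolidate/interpret chain for one template.

    Sites supported by fewer than ``min_site_support`` band observations
    across the whole lane set are discarded (preferential sites are averages
    over at least two observations).
    """
    template = templates.build_template(name, genotype=genotype, variant=variant)
    time_points = tuple(sorted({0.0, *(t for t, _ in schedule)}))
    params = chec_sim.DigestionParams(
        n_molecules=n_molecules,
        time_points=time_points,
        base_rate=base_rate,
        seed=chec_sim.derive_seed(seed, "experiment", name, genotype, variant),
    )
    populations = chec_sim.simulate_experiment(template, constructs, params, schedule)

    true_cal = gel.DEFAULT_CALIBRATION
    ladder_rng = np.random.default_rng(chec_sim.derive_seed(seed, "ladder", name))
    ladder = gel.make_ladder(true_cal, noise_sd=ladder_noise, rng=ladder_rng)
    calibration = gel.calibrate(ladder)

    exclude = exclusion_size(template)
    lane_bands = {}
    observations = []
    for pop in populations:
        profile = gel.render_lane(pop, true_cal, ladder=ladder)
        prom = min_prominence
        if pop.lane.construct == "H2A-MN" and pop.lane.temperature == "4C":
            prom = h2a_cold_prominence
        bands = caller.detect_bands(profile, calibration, prom,
                                    exclude_size_above=exclude)
        lane_bands[pop.lane] = bands
        offsets = caller.sizes_to_cut_offsets(bands, template)
        for b, off in zip(bands, offsets):
            observations.append(
                caller.SiteObservation(float(off), pop.lane.construct, pop.lane,
                                       b.percent_signal)
            )

    sites = caller.consolidate(
        observations, tolerance, template.label_order, template=template.name
    )
    sites = [s for s in sites if s.n_observations >= min_site_support]
    sites = _relabel(sites, template.label_order)
    intervals = inference.classify_intervals(sites, template, classifier_threshold)
    model = inference.reconstruct_model(intervals, template)
    ratios = {}
    if template.name in inference.RATIO_SPECS:
        for construct in constructs:
            ratios[construct] = inference.accessibility_ratio(
                lane_bands, sites, template, construct
            )
    return TemplateResult(
        template=template,
        populations=populations,
        lane_bands=lane_bands,
        sites=sites,
        intervals=intervals,
        model=model,
        ratios=ratios,
        calibration=calibration,
    )


def _relabel(sites, label_order):
    """Re-assign Roman labels after support filtering (labels stay dense)."""
    ordered = sorted(sites, key=lambda s: s.mean_offset,
                     reverse=(label_order == "distal_first"))
    out = []
    from dataclasses import replace

    for k, s in enumerate(ordered):
        out.append(replace(s, label=caller._roman(k + 1)))
    out.sort(key=lambda s: s.mean_offset)
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the configured templates and (optionally) write the result bundle."""
    results = {}
    for name in config.templates:
        try:
            results[name] = analyze_template(
                name,
                seed=config.seed,
                n_molecules=config.n_molecules,
                constructs=config.constructs,
                genotype=config.genotype,
                base_rate=config.base_rate,
                schedule=config.schedule,
                tolerance=config.tolerance,
                min_prominence=config.min_prominence,
                h2a_cold_prominence=config.h2a_cold_prominence,
                classifier_threshold=config.classifier_threshold,
                ladder_noise=config.ladder_noise,
            )
        except Exception as e:  # annotate with the failing stage
            raise RuntimeError(f"pipeline failed on template {name}: {e}") from e
    result = PipelineResult(config=config, results=results)
    if config.outdir:
        write_bundle(result, Path(config.outdir))
    return result


def run_foldback_report(seed: int, n_molecules: int = 1200) -> dict:
    """Fold-back discrimination across genotypes and contexts, both modes."""
    out = {}
    for mode in ("direct_binding", "foldback"):
        params = chec_sim.DigestionParams(
            n_molecules=n_molecules, seed=chec_sim.derive_seed(seed, "foldback", mode)
        )
        ref = inference.foldback_test(mode, "WT", "chromosomal", params)
        out[(mode, "WT", "chromosomal")] = ref
        for genotype, context in (("sir", "chromosomal"), ("yku", "chromosomal"),
                                  ("WT", "plasmid")):
            out[(mode, genotype, context)] = inference.foldback_test(
                mode, genotype, context, params, reference_sites=ref.sites
            )
    return out


def write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, res in result.results.items():
        io.write_lanes_tsv(res.populations, outdir / f"{name}.lanes.tsv")
        io.bands_to_frame(res.lane_bands).to_csv(
            outdir / f"{name}.bands.tsv", sep="\t", index=False, float_format="%.4f"
        )
        io.sites_to_frame(res.sites).to_csv(
            outdir / f"{name}.sites.tsv", sep="\t", index=False, float_format="%.4f"
        )
        io.write_sites_bed(res.sites, outdir / f"{name}.sites.bed")
        io.intervals_to_frame(res.intervals).to_csv(
            outdir / f"{name}.intervals.tsv", sep="\t", index=False, float_format="%.4f"
        )
        with open(outdir / f"{name}.model.tsv", "w") as fh:
            fh.write("left\tright\toccupant\n")
            for lo, hi, kind in res.model.occupants:
                fh.write(f"{lo:.1f}\t{hi:.1f}\t{kind}\n")
            fh.write(f"# terminal_nfr={res.model.terminal_nfr}"
                     f" orc_site={res.model.orc_site} abf1_site={res.model.abf1_site}\n")
    manifest = {
        "config_digest": result.config.digest(),
        "seed": result.config.seed,
        "templates": list(result.config.templates),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
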