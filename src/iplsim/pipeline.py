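"""End-to-end comparison pipeline.

Transport is executed exactly once per comparison -- the absorption map
per unit fluence does not depend on the pulse shape -- and the thermal
solver is then run once per pulse category against the shared map.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

from . import __version__
from .config import RunConfig, config_hash, dump_config
from .pulses import PulseCategory, envelope_duration, standard_train
from .report import ComparisonReport, write_report
from .thermal import peak_metrics, run_simulation
from .tissue import GeometryConfig, build_grid, locate_probes
from .transport import run_transport, save_absorption

log = logging.getLogger("iplsim")


def run_comparison(config: RunConfig, quiet: bool = False) -> ComparisonReport:
    """Run the full experiment described by ``config``.

    Builds the grid and spectrum, runs the Monte Carlo transport once,
    then one thermal simulation per requested pulse category; returns the
    comparison report (and writes traces/report/absorption if the config
    names an output directory).
    """
    if not quiet:
        log.info("building grid and spectrum")
    grid = build_grid(config.geometry, config.optics)
    spectrum = config.spectrum.build(total_fluence=config.fluence)
    probes = locate_probes(grid)

    t0 = time.perf_counter()
    if not quiet:
        log.info("transport: %d photons, seed %d", config.n_photons, config.seed)
    try:
        absorption, tally = run_transport(grid, spectrum, config.n_photons,
                                          config.seed)
    except Exception as exc:
        raise RuntimeError(f"transport stage failed: {exc}") from exc
    if not quiet:
        log.info("transport done in %.1f s (absorbed fraction %.3f)",
                 time.perf_counter() - t0, tally.absorbed)

    histories = {}
    trains = {}
    for cat in config.categories:
        cat = PulseCategory(cat)
        train = standard_train(cat)
        trains[cat.value] = {
            "n_pulses": train.n_pulses,
            "energy_per_pulse": train.energy_per_pulse,
            "envelope_s": envelope_duration(train),
            "segments": [dataclasses.asdict(s) for s in train.segments],
        }
        t0 = time.perf_counter()
        try:
            histories[cat] = run_simulation(absorption, train, grid,
                                            config.solver, config.fluence,
                                            probes=probes)
        except Exception as exc:
            raise RuntimeError(
                f"thermal stage failed for category {cat.value!r}: {exc}") from exc
        if not quiet:
            log.info("thermal %s: peak epidermis %.1f C, follicle %.1f C (%.1f s)",
                     cat.value, histories[cat].peak_epidermal,
                     histories[cat].peak_follicle, time.perf_counter() - t0)

    if set(histories) == set(PulseCategory):
        metrics = peak_metrics(histories, threshold=config.damage_threshold)
        excess = metrics.excess_percent
        exceeds = metrics.exceeds_threshold
    else:
        excess = {}
        exceeds = {c.value: bool(h.peak_follicle >= config.damage_threshold)
                   for c, h in histories.items()}

    report = ComparisonReport(
        provenance={
            "seed": config.seed,
            "n_photons": config.n_photons,
            "fluence_J_cm2": config.fluence,
            "config_hash": config_hash(config),
            "version": __version__,
        },
        tally=dataclasses.asdict(tally),
        peak_epidermal={c.value: h.peak_epidermal for c, h in histories.items()},
        peak_follicle={c.value: h.peak_follicle for c, h in histories.items()},
        rise_epidermal={c.value: h.peak_epidermal_rise for c, h in histories.items()},
        rise_follicle={c.value: h.peak_follicle_rise for c, h in histories.items()},
        excess_percent=excess,
        exceeds_threshold=exceeds,
        threshold=config.damage_threshold,
        pulse_trains=trains,
        traces={c.value: {"times": h.times, "epidermal": h.epidermal_trace,
                          "follicle": h.follicle_trace}
                for c, h in histories.items()},
    )
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir)
        save_absorption(outdir / "absorption.npz", absorption)
        dump_config(config, outdir / "config.yaml")
        if not quiet:
            log.info("report written to %s", outdir)
    return report


def make_fixture(kind: str) -> RunConfig:
    """Small deterministic configurations for CI and quick checks.

    ``tiny_grid``: 100x100 cells with a shallow follicle; ``homogeneous_slab``:
    uniform dermis below the epidermis (no follicle, probes repointed to
    dermis depth); ``no_follicle``: like tiny_grid but without the follicle,
    so probe location raises the documented error.
    """
    import dataclasses as dc
    if kind == "tiny_grid":
        geo = GeometryConfig(domain_width=500e-6, domain_depth=500e-6,
                             follicle_top_depth=150e-6, follicle_diameter=100e-6,
                             follicle_length=250e-6, probe_follicle_depth=300e-6)
    elif kind in ("homogeneous_slab", "no_follicle"):
        geo = GeometryConfig(domain_width=500e-6, domain_depth=500e-6,
                             follicle_diameter=0.0, follicle_length=0.0,
                             follicle_top_depth=0.0, probe_follicle_depth=300e-6)
        if kind == "homogeneous_slab":
            geo = dc.replace(geo, epidermis_thickness=0.0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RunConfig(geometry=geo, n_photons=20_000, seed=777,
                         solver=dc.replace(RunConfig().solver, cooling_tail=0.005))
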