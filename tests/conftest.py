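"""Shared fixtures: small synthetic runs and a session-scoped 20-seed
pipeline cache consumed by the property and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from diadeconv import cli, pasef_sim

#: Fixed seed panel for all multi-seed statistical contracts.
SEEDS = tuple(range(1, 21))


def small_sim_config(seed: int = 7, **overrides) -> pasef_sim.SimConfig:
    """A fast, small run: 5 species, 10 cycles, 3 windows."""
    kwargs = dict(
        rng_seed=seed,
        n_species=5,
        gradient_length_s=30.0,
        cycle_time_s=3.0,
        noise_density=30,
    )
    kwargs.update(overrides)
    return pasef_sim.SimConfig(**kwargs)


def default_pipeline_config(**overrides) -> cli.PipelineConfig:
    """Pipeline defaults used for simulated data throughout the suite.

    ``min_seed_intensity`` is raised above the chemical-noise floor of the
    simulator (isolated noise points survive aggregation at ~20-150 counts);
    every other knob is the package default.
    """
    cfg = cli.PipelineConfig(min_seed_intensity=30.0)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@dataclass
class SeedResult:
    seed: int
    species: list
    ms1_features: list
    ms2_by_window: dict
    precursors: list
    spectra: list
    merged_frame_spacing: float


def run_seed(seed: int, n_species: int = 50) -> SeedResult:
    cfg = pasef_sim.SimConfig(rng_seed=seed, n_species=n_species)
    run, species = pasef_sim.simulate_run(cfg)
    pcfg = default_pipeline_config()
    ms1, ms2w, precs, spectra = cli.deconvolute_run(run, pcfg)
    return SeedResult(
        seed=seed,
        species=species,
        ms1_features=ms1,
        ms2_by_window=ms2w,
        precursors=precs,
        spectra=spectra,
        merged_frame_spacing=cfg.cycle_time_s,
    )


@pytest.fixture(scope="session")
def multi_seed_runs() -> list[SeedResult]:
    """Full pipeline on 20 seeds x 50 species; computed once per session."""
    return [run_seed(seed) for seed in SEEDS]


@pytest.fixture(scope="session")
def single_run():
    """One simulated run kept with its fixture object for oracle tests."""
    cfg = pasef_sim.SimConfig(rng_seed=1, n_species=50)
    run, species = pasef_sim.simulate_run(cfg)
    return run, species


@pytest.fixture()
def small_run():
    run, species = pasef_sim.simulate_run(small_sim_config())
    return run, species


# ---------------------------------------------------------------------------
# ground-truth matching helpers


def match_precursor(species, precursors, ppm_window: float = 30.0,
                    rt_window: float = 4.5, im_window: float = 0.02):
    """The recovered precursor closest in m/z to a planted species, or None."""
    best = None
    for p in precursors:
        dppm = (abs(p.monoisotopic_mz - species.monoisotopic_mz)
                / species.monoisotopic_mz * 1e6)
        if (dppm < ppm_window
                and abs(p.apex_rt - species.rt_apex) < rt_window
                and abs(p.apex_im - species.im_apex) < im_window):
            if best is None or dppm < best[0]:
                best = (dppm, p)
    return best
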