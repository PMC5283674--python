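"""Benchmark scenario definitions on the synthetic Shepp-Logan phantom.

Each scenario fixes the degradation (blur family + mean-one Gamma noise
level), the solver weights used for it, and the RNG seed, so the whole
benchmark regenerates from code.  The solver weights were tuned once on
the phantom within the model's stated ranges and are kept fixed.
"""

from __future__ import annotations

from .cli_io import RunConfig
from .degrade import BlurSpec, NoiseSpec
from .solver import InnerConfig, SolverConfig


def phantom_solver_config(scenario: str, max_iter: int | None = None,
                          seed: int = 0) -> SolverConfig:
    """Tuned solver settings for the phantom benchmark scenarios.

    ``scenario`` is one of ``denoise_L10``, ``denoise_L6``,
    ``motion_L10``, ``gaussian_L10``, ``multichannel``.
    """
    base = dict(
        lam=0.05, alpha=5.0, gamma1=0.8, gamma0=1.6,
        mu1=10.0, mu2=10.0, mu3=10.0, mu=1.0,
        max_iter=700, tol=2e-5, n_scales=3,
        penalize_lowpass=False, seed=seed,
    )
    overrides = {
        "denoise_L10": {},
        "denoise_L6": {},
        "motion_L10": {"gamma1": 0.9, "gamma0": 1.8, "max_iter": 300},
        "gaussian_L10": {"gamma1": 1.4, "gamma0": 2.8, "max_iter": 300},
        "multichannel": {"max_iter": 150},
    }
    if scenario not in overrides:
        raise ValueError(f"unknown scenario {scenario!r}")
    base.update(overrides[scenario])
    if max_iter is not None:
        base["max_iter"] = max_iter
    return SolverConfig(**base)


def scenario_blur(scenario: str) -> BlurSpec:
    """Degrading blur of a benchmark scenario."""
    if scenario in ("denoise_L10", "denoise_L6", "multichannel"):
        return BlurSpec("identity")
    if scenario == "motion_L10":
        return BlurSpec("motion", {"length": 5, "angle": 30})
    if scenario == "gaussian_L10":
        return BlurSpec("gaussian", {"hsize": 7, "sigma": 2})
    raise ValueError(f"unknown scenario {scenario!r}")


def scenario_noise(scenario: str, seed: int = 0) -> NoiseSpec:
    """Degrading noise of a benchmark scenario."""
    if scenario in ("denoise_L10", "motion_L10", "gaussian_L10"):
        return NoiseSpec("gamma", L=10, seed=seed)
    if scenario == "denoise_L6":
        return NoiseSpec("gamma", L=6, seed=seed)
    if scenario == "multichannel":
        return NoiseSpec("speckle_variance", sigma2=0.1, seed=seed)
    raise ValueError(f"unknown scenario {scenario!r}")


def scenario_run_config(scenario: str, size: int = 256, seed: int = 0,
                        max_iter: int | None = None) -> RunConfig:
    solver = phantom_solver_config(scenario, max_iter=max_iter, seed=seed)
    blur = scenario_blur(scenario)
    noise = scenario_noise(scenario, seed=seed)
    if scenario == "multichannel":
        return RunConfig(fixture="phantom", size=size, blur=blur,
                         noise=noise, solver=solver, channels=3,
                         cross_channel="identity")
    return RunConfig(fixture="phantom", size=size, blur=blur, noise=noise,
                     solver=solver)


def suite_scenarios(name: str, size: int = 256,
                    max_iter: int | None = None) -> list:
    """Scenario lists for the named experiment suite."""
    if name == "table4":
        labels = ["denoise_L10", "denoise_L6"]
    elif name == "table5":
        labels = ["motion_L10", "gaussian_L10"]
    elif name == "multichannel":
        labels = ["multichannel"]
    else:
        raise ValueError(f"unknown suite {name!r}")
    return [(lbl, scenario_run_config(lbl, size=size, max_iter=max_iter))
            for lbl in labels]
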