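"""Synthetic tensile-test curves and traces with controlled noise.

The generator uses the constitutive model itself as the kernel: a uniform
strain grid on [0, eps_p], model stress at each strain, then measurement
noise.  Noise is multiplicative Gaussian on stress by default — load-cell
error scales with load, and the tester class used for such work is rated
at +-0.5 % of reading, hence the 0.005 default relative level — with an
additive alternative available.  Two conventions matter downstream:

* the exact peak sample (eps_p, sigma_p) is always included noise-free,
  and every other sample is capped strictly below sigma_p, so the
  dimensionless peak is identified exactly and estimator bias can be
  separated from peak-detection error (near the peak the curve is flat, so
  uncapped noise would routinely push samples above sigma_p and migrate
  the detected peak);
* in necking mode a post-peak tail is appended at stresses held strictly
  below sigma_p (a small linear decay), emulating the minority of tests
  where deformation continues past peak stress; only the tail's existence
  matters for truncation behaviour, not its exact shape.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .constitutive import RootMaterialParams, dimensional_stress
from .estimation import StressStrainCurve, fit_curve, plug_in_modulus_ratio
from .machine_io import RawTensileTrace, SpecimenMeta, curve_to_trace, write_trace_csv
from .presets import table2_presets

__all__ = [
    "GeneratorConfig",
    "generate_curve",
    "generate_trace",
    "recovery_experiment",
    "write_trace_dataset",
    "preset_configs",
]

BREAK_AT_PEAK = "break_at_peak"
NECKING_PLATEAU = "necking_plateau"

#: Fractional stress drop across a necking tail (tail stays below sigma_p).
_TAIL_DECAY = 0.05


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for one synthetic test.

    noise_sd is the relative (multiplicative mode) or absolute-in-units-of-
    sigma_p (additive mode) standard deviation of the stress noise;
    tail_fraction is extra strain beyond eps_p as a fraction of eps_p,
    used only in necking mode.
    """

    params: RootMaterialParams
    n_points: int = 200
    noise_sd: float = 0.005
    seed: int = 0
    post_peak_mode: str = BREAK_AT_PEAK
    tail_fraction: float = 0.2
    noise_model: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.n_points < 10:
            raise ValueError(f"n_points must be >= 10 (got {self.n_points})")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0 (got {self.noise_sd})")
        if self.tail_fraction < 0:
            raise ValueError(
                f"tail_fraction must be >= 0 (got {self.tail_fraction})"
            )
        if self.post_peak_mode not in (BREAK_AT_PEAK, NECKING_PLATEAU):
            raise ValueError(f"unknown post_peak_mode {self.post_peak_mode!r}")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _apply_noise(
    clean: np.ndarray, eta: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    if config.noise_model == "multiplicative":
        noisy = clean * (1.0 + eta)
    else:
        noisy = clean + config.noise_sd * config.params.sigma_p * eta
    return np.clip(noisy, 0.0, None)


def generate_curve(
    config: GeneratorConfig,
) -> tuple[StressStrainCurve, RootMaterialParams]:
    """One synthetic stress-strain curve plus its generating parameters.

    The pre-peak grid is uniform on [0, eps_p] with n_points samples; the
    final sample is exactly (eps_p, sigma_p), noise-free.  In necking mode
    a tail of round(tail_fraction * n_points) extra samples (at least one)
    extends the strain to eps_p*(1 + tail_fraction) at stresses strictly
    below sigma_p.  Pre-peak samples are identical across post-peak modes
    for the same seed: tail noise is drawn after all pre-peak noise.
    """
    p = config.params
    rng = np.random.default_rng(config.seed)
    eps = np.linspace(0.0, p.eps_p, config.n_points)
    clean = np.asarray(dimensional_stress(eps, p))
    eta = rng.normal(0.0, config.noise_sd, config.n_points)
    stress = _apply_noise(clean, eta, config)
    # cap noisy samples strictly below the peak so the noise-free peak
    # sample is the unique maximum and (eps_p, sigma_p) stay identifiable
    np.minimum(stress, p.sigma_p * (1.0 - 1e-9), out=stress)
    stress[0] = 0.0
    stress[-1] = p.sigma_p  # exact, noise-free peak

    if config.post_peak_mode == NECKING_PLATEAU and config.tail_fraction > 0:
        n_tail = max(1, round(config.tail_fraction * config.n_points))
        t = np.arange(1, n_tail + 1) / n_tail
        eps_tail = p.eps_p * (1.0 + config.tail_fraction * t)
        clean_tail = p.sigma_p * (1.0 - _TAIL_DECAY * t)
        eta_tail = rng.normal(0.0, config.noise_sd, n_tail)
        stress_tail = _apply_noise(clean_tail, eta_tail, config)
        # keep the tail strictly below the peak so the peak never migrates
        stress_tail = np.minimum(stress_tail, p.sigma_p * (1.0 - 1e-9))
        eps = np.concatenate([eps, eps_tail])
        stress = np.concatenate([stress, stress_tail])

    return StressStrainCurve(strain=eps, stress=stress), p


def generate_trace(config: GeneratorConfig, meta: SpecimenMeta) -> RawTensileTrace:
    """Synthetic machine trace: the generated curve mapped to (mm, N)."""
    curve, _ = generate_curve(config)
    return curve_to_trace(curve, meta)


def recovery_experiment(
    configs: Union[GeneratorConfig, Sequence[GeneratorConfig]],
    n_reps: int,
    seed: int,
    *,
    q: float = 0.4,
) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE of the estimation pipeline.

    For each configuration, ``n_reps`` curves are generated (replicate r of
    configuration i uses seed ``seed + 100000*i + r``) and fitted.  Bias
    and RMSE of the E0, Ep and E estimates are reported against two
    references: the generating parameters ("truth") and the plug-in values
    the secant estimator converges to on noiseless data ("plugin", where
    E_plug = plug_in_modulus_ratio(E_true, q), E0_plug = E_plug * Ep, and
    Ep_plug = Ep).  At zero noise the plugin-referenced errors vanish up to
    grid-interpolation error while the truth-referenced E0/E errors expose
    the estimator's inherent (negative) bias.
    """
    if isinstance(configs, GeneratorConfig):
        configs = [configs]
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    records = []
    for i, cfg in enumerate(configs):
        truth = cfg.params
        E_true = truth.E
        E_plug = plug_in_modulus_ratio(E_true, q)
        refs = {
            "truth": {"E0": truth.E0, "Ep": truth.Ep, "E": E_true},
            "plugin": {"E0": E_plug * truth.Ep, "Ep": truth.Ep, "E": E_plug},
        }
        est = {"E0": [], "Ep": [], "E": []}
        for r in range(n_reps):
            curve, _ = generate_curve(replace(cfg, seed=seed + 100000 * i + r))
            fit = fit_curve(curve, q)
            est["E0"].append(fit.E0)
            est["Ep"].append(fit.Ep)
            est["E"].append(fit.E)
        rec: dict[str, object] = {
            "config": i,
            "noise_sd": cfg.noise_sd,
            "n_points": cfg.n_points,
            "n_reps": n_reps,
        }
        for param in ("E0", "Ep", "E"):
            e = np.asarray(est[param])
            for ref_name, ref in refs.items():
                err = e - ref[param]
                rec[f"bias_{param}_{ref_name}"] = float(err.mean())
                rec[f"rmse_{param}_{ref_name}"] = float(
                    np.sqrt(np.mean(err**2))
                )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_trace_dataset(
    out_dir: Union[str, Path],
    configs: dict[str, GeneratorConfig],
    metas: dict[str, SpecimenMeta],
    *,
    delimiter: str = ",",
) -> Path:
    """Write one trace CSV per specimen plus metadata and ground truth.

    Produces ``<id>.csv`` trace files, ``metadata.csv`` (specimen_id,
    species, diameter_mm, gauge_mm, trace_path) and a ``ground_truth.json``
    sidecar mapping specimen ids to generating parameters and seeds.
    Returns the metadata path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    truth: dict[str, dict] = {}
    for specimen_id, cfg in configs.items():
        meta = metas[specimen_id]
        trace = generate_trace(cfg, meta)
        trace_path = out / f"{specimen_id}.csv"
        write_trace_csv(trace, trace_path, delimiter=delimiter)
        meta_rows.append({
            "specimen_id": specimen_id,
            "species": meta.species,
            "diameter_mm": meta.diameter,
            "gauge_mm": meta.gauge_length,
            "trace_path": trace_path.name,
        })
        p = cfg.params
        truth[specimen_id] = {
            "sigma_p": p.sigma_p, "eps_p": p.eps_p,
            "E0": p.E0, "Ep": p.Ep, "E": p.E,
            "noise_sd": cfg.noise_sd, "n_points": cfg.n_points,
            "seed": cfg.seed, "post_peak_mode": cfg.post_peak_mode,
        }
    meta_path = out / "metadata.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep=delimiter, index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return meta_path


def preset_configs(
    seed: int,
    *,
    noise_sd: float = 0.005,
    n_points: int = 200,
    sigma_p: float | None = None,
    post_peak_mode: str = BREAK_AT_PEAK,
) -> dict[str, GeneratorConfig]:
    """One generator configuration per published preset group.

    Specimen i gets seed ``seed + i`` so a dataset is reproducible from a
    single integer.
    """
    kwargs = {} if sigma_p is None else {"sigma_p": sigma_p}
    presets = table2_presets(**kwargs)
    return {
        name: GeneratorConfig(
            params=params, n_points=n_points, noise_sd=noise_sd,
            seed=seed + i, post_peak_mode=post_peak_mode,
        )
        for i, (name, params) in enumerate(presets.items())
    }
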