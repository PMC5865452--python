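"""Synthetic cohorts of coupled stochastic phase oscillators.

Each channel's band-limited hemodynamic oscillation is modelled as a phase
oscillator

    dphi_k = [omega_k + sum_c eps_c * f_c(phi_src, phi_k)] dt + sigma_k dW_k

integrated by Euler-Maruyama with internal oversampling, then projected to
an observable signal x_k(t) = A_k cos(phi_k(t)) plus broadband observation
noise and an optional sub-0.005 Hz drift.  Directed couplings are injected
per (group, posture state, frequency band), so every downstream stage of
the pipeline can be validated by parameter recovery against the generated
ground-truth ledger.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrationError
from .io_fnirs import (
    ChannelLayout, Recording, standard_layout, write_manifest,
    write_recording,
)

#: the two analysis bands (Hz): I myogenic, II neurogenic
BANDS = {"I": (0.052, 0.145), "II": (0.021, 0.052)}


def derive_seed(base: int, *keys) -> int:
    """Deterministic child seed < 2**31 from a base seed and string/int keys."""
    h = zlib.crc32(repr((int(base),) + tuple(keys)).encode())
    return int(h % (2**31 - 1))


@dataclass(frozen=True)
class OscillatorSpec:
    """One phase oscillator: natural frequency (Hz), signal amplitude
    (concentration units) and phase-diffusion SD (rad * s**-0.5)."""

    natural_freq: float
    amplitude: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.natural_freq <= 0:
            raise ConfigError("natural_freq must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Directed coupling term eps * func(k_source*phi_src + k_target*phi_tgt)
    added to the target oscillator's phase velocity (rad/s).

    Defaults give the canonical sine difference coupling
    eps * sin(phi_source - phi_target).  Channels are 1-based.
    """

    source: int
    target: int
    epsilon: float
    k_source: int = 1
    k_target: int = -1
    func: str = "sin"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ConfigError("coupling source must differ from target")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if self.func not in ("sin", "cos"):
            raise ConfigError("func must be 'sin' or 'cos'")


def simulate_phases(
    specs: list[OscillatorSpec],
    couplings: list[CouplingSpec],
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    dt_max: float = 0.01,
) -> np.ndarray:
    """Integrate the coupled phase SDE; returns unwrapped phases (n_osc, n).

    Euler-Maruyama with internal step <= dt_max seconds, decimated to fs.
    Initial phases are uniform on [0, 2*pi).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_osc = len(specs)
    for c in couplings:
        if not (1 <= c.source <= n_osc and 1 <= c.target <= n_osc):
            raise ConfigError(f"coupling references channel outside 1..{n_osc}")
    over = max(1, math.ceil((1.0 / fs) / dt_max))
    dt = 1.0 / (fs * over)
    n_out = int(round(duration_s * fs))
    omega = 2 * np.pi * np.array([s.natural_freq for s in specs])
    sigma = np.array([s.noise_sd for s in specs])
    sq = sigma * math.sqrt(dt)
    src = np.array([c.source - 1 for c in couplings], dtype=int)
    tgt = np.array([c.target - 1 for c in couplings], dtype=int)
    eps = np.array([c.epsilon for c in couplings])
    ks = np.array([c.k_source for c in couplings])
    kt = np.array([c.k_target for c in couplings])
    is_sin = np.array([c.func == "sin" for c in couplings])

    phi = rng.uniform(0.0, 2 * np.pi, size=n_osc)
    out = np.empty((n_osc, n_out))
    noisy = np.any(sigma > 0)
    noise = (
        rng.standard_normal((n_out * over, n_osc)) * sq if noisy else None
    )
    base_step = omega * dt
    coupled = len(couplings) > 0
    step = 0
    for i in range(n_out):
        prev = phi.copy()
        for _ in range(over):
            if coupled:
                arg = ks * phi[src] + kt * phi[tgt]
                term = eps * np.where(is_sin, np.sin(arg), np.cos(arg))
                incr = base_step.copy()
                np.add.at(incr, tgt, term * dt)
                phi = phi + incr
            else:
                phi = phi + base_step
            if noisy:
                phi = phi + noise[step]
            step += 1
        if np.any(np.abs(phi - prev) > np.pi):
            raise IntegrationError(
                f"|delta phi| > pi at sample {i}; reduce the step or noise"
            )
        out[:, i] = phi
    return out


def in_band_noise_sd(
    amplitude: float, snr_db: float, band: tuple[float, float], fs: float
) -> float:
    """White-noise SD giving the requested in-band SNR for a cos carrier.

    White noise of SD sigma spreads its power evenly over (0, fs/2); only
    the fraction inside ``band`` competes with the oscillation, whose power
    is amplitude**2 / 2.
    """
    f_lo, f_hi = band
    frac = (f_hi - f_lo) / (fs / 2)
    sig_power = amplitude**2 / 2
    inband = sig_power / 10 ** (snr_db / 10)
    return math.sqrt(inband / frac)


def phases_to_signal(
    phases: np.ndarray,
    specs: list[OscillatorSpec],
    fs: float,
    observation_noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    drift_freq: float = 0.002,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Project unwrapped phases to observable signals (n_osc, n).

    x_k = A_k cos(phi_k) + white observation noise + optional slow drift
    below the 0.005 Hz pre-processing cutoff (to exercise the band-pass).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phases = np.asarray(phases, dtype=float)
    amp = np.array([s.amplitude for s in specs])[:, None]
    x = amp * np.cos(phases)
    n = phases.shape[1]
    if drift_amplitude > 0:
        t = np.arange(n) / fs
        ph0 = rng.uniform(0, 2 * np.pi, size=(phases.shape[0], 1))
        x = x + drift_amplitude * np.sin(2 * np.pi * drift_freq * t + ph0)
    if observation_noise_sd > 0:
        x = x + observation_noise_sd * rng.standard_normal(x.shape)
    return x


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class RegionCoupling:
    """A directed region-level coupling applied to a (group, state, band)
    cell; ``group``/``state`` of None match every group/state.  Expanded to
    all (source-region channel, target-region channel) pairs."""

    source_region: str
    target_region: str
    epsilon: float
    band: str = "II"
    group: str | None = None
    state: str | None = None


def default_coupling_table() -> list[RegionCoupling]:
    """Study-condition couplings: a baseline LPFC->RPFC interaction in the
    neurogenic band for every group/state, elevated in elderly standing
    (the posture contrast the elderly group shows in that band)."""
    return [
        RegionCoupling("LPFC", "RPFC", 0.2, band="II"),
        RegionCoupling("LPFC", "RPFC", 0.5, band="II",
                       group="elderly", state="standing"),
    ]


#: demographic distributions: (mean, SD) per group
DEMOGRAPHICS = {
    "elderly": {"age": (69.4, 9.6), "bmi": (19.2, 3.2), "mmse": (27.5, 1.5),
                "p_female": 5 / 18},
    "young": {"age": (24.1, 1.9), "bmi": (18.5, 4.2), "mmse": (29.3, 0.6),
              "p_female": 7 / 20},
}


@dataclass
class CohortConfig:
    """Cohort-level generation parameters.

    Defaults reproduce the study conditions: 17 elderly + 19 young subjects,
    sitting and standing recordings of >= 10 min at 10 Hz over the 36-channel
    montage, oscillators in both analysis bands with +/-10% frequency jitter,
    10 dB in-band observation SNR, and the default coupling table.
    """

    n_elderly: int = 17
    n_young: int = 19
    states: tuple[str, ...] = ("sitting", "standing")
    duration_s: float = 600.0
    fs: float = 10.0
    layout: ChannelLayout = field(default_factory=standard_layout)
    bands: dict = field(default_factory=lambda: dict(BANDS))
    phase_noise_sd: float = 0.2
    amplitude: float = 1.0
    snr_db: float = 10.0
    drift_amplitude: float = 0.5
    freq_jitter: float = 0.10
    couplings: list[RegionCoupling] = field(
        default_factory=default_coupling_table
    )
    #: per-subject couplings scale by (1 + coupling_cv * z_s), z_s ~ N(0,1)
    coupling_cv: float = 0.25
    #: elderly MMSE correlates with the subject coupling factor at this r
    mmse_coupling_r: float = 0.7
    seed: int = 0
    file_format: str = "csv"

    def __post_init__(self) -> None:
        if self.duration_s * self.fs < 2**12:
            raise ConfigError(
                "duration_s * fs must be >= 4096 samples for band resolution"
            )


#: order in which regions take their slot on the within-band frequency
#: ladder; interleaved so that homotopic pairs (e.g. LPFC/RPFC) are well
#: detuned and their relative phase keeps running (a phase-locked pair is
#: unidentifiable for coupling inference)
_REGION_FREQ_SLOT = {"LPFC": 0, "RPFC": 5, "LMC": 1, "RMC": 4,
                     "LOL": 2, "ROL": 3}


def region_center_freqs(
    layout: ChannelLayout, f_lo: float, f_hi: float
) -> dict[str, float]:
    """Per-region natural-frequency centres spread across the band interior."""
    n = len(layout.labels)
    grid = np.linspace(1.15 * f_lo, 0.85 * f_hi, max(n, 2))
    return {
        label: float(grid[_REGION_FREQ_SLOT.get(label, i) % len(grid)])
        for i, label in enumerate(layout.labels)
    }


def _expand_couplings(
    table: list[RegionCoupling], layout: ChannelLayout,
    group: str, state: str, band: str, factor: float,
) -> list[CouplingSpec]:
    # later table entries override earlier ones for the same channel pair
    eff: dict[tuple[int, int], float] = {}
    for rc in table:
        if rc.band != band:
            continue
        if rc.group is not None and rc.group != group:
            continue
        if rc.state is not None and rc.state != state:
            continue
        for i in layout.channels_in(rc.source_region):
            for j in layout.channels_in(rc.target_region):
                if i != j:
                    eff[(int(i), int(j))] = rc.epsilon * factor
    return [
        CouplingSpec(source=i, target=j, epsilon=e)
        for (i, j), e in sorted(eff.items())
    ]


def generate_cohort(
    config: CohortConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, dict]:
    """Write one recording per (subject, state), a manifest and a ground-truth
    ledger; returns (manifest DataFrame, ledger dict).

    Fully deterministic given ``config.seed``: all randomness flows through
    seeds derived from (seed, subject, state, band, purpose).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = config.layout
    subjects = (
        [("elderly", f"E{i + 1:02d}") for i in range(config.n_elderly)]
        + [("young", f"Y{i + 1:02d}") for i in range(config.n_young)]
    )
    ids = [s for _, s in subjects]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate subject ids in cohort")

    ledger: dict = {
        "seed": config.seed,
        "bands": {k: list(v) for k, v in config.bands.items()},
        "mmse_coupling_r": config.mmse_coupling_r,
        "subjects": {},
    }
    rows = []
    ext = "snirf" if config.file_format == "snirf" else "csv"
    for group, sid in subjects:
        demo_rng = np.random.default_rng(derive_seed(config.seed, sid, "demo"))
        d = DEMOGRAPHICS[group]
        z = demo_rng.standard_normal()  # shared latent: coupling factor
        w = demo_rng.standard_normal()
        r = config.mmse_coupling_r
        mmse = d["mmse"][0] + d["mmse"][1] * (r * z + math.sqrt(1 - r**2) * w)
        mmse = float(np.clip(mmse, 0.0, 30.0))
        age = float(demo_rng.normal(*d["age"]))
        bmi = float(demo_rng.normal(*d["bmi"]))
        sex = "F" if demo_rng.uniform() < d["p_female"] else "M"
        factor = max(0.0, 1.0 + config.coupling_cv * z)
        sub_entry = {
            "group": group, "coupling_factor": factor, "mmse": mmse,
            "states": {},
        }
        paths = {}
        for state in config.states:
            n = int(round(config.duration_s * config.fs))
            total = np.zeros((layout.n_channels, n))
            state_entry = {}
            for band_name, (f_lo, f_hi) in config.bands.items():
                brng = np.random.default_rng(
                    derive_seed(config.seed, sid, state, band_name, "osc")
                )
                centers = region_center_freqs(layout, f_lo, f_hi)
                base_freq = np.array([
                    centers[layout.region_of(ch)]
                    for ch in layout.channel_ids
                ])
                jitter = brng.uniform(
                    1 - config.freq_jitter, 1 + config.freq_jitter,
                    size=layout.n_channels,
                )
                freqs = np.clip(base_freq * jitter, f_lo, f_hi)
                specs = [
                    OscillatorSpec(
                        natural_freq=float(f), amplitude=config.amplitude,
                        noise_sd=config.phase_noise_sd,
                    )
                    for f in freqs
                ]
                coups = _expand_couplings(
                    config.couplings, layout, group, state, band_name, factor
                )
                phases = simulate_phases(
                    specs, coups, config.duration_s, config.fs,
                    seed=np.random.default_rng(
                        derive_seed(config.seed, sid, state, band_name, "sde")
                    ),
                )
                sig = phases_to_signal(
                    phases, specs, config.fs,
                    observation_noise_sd=in_band_noise_sd(
                        config.amplitude, config.snr_db, (f_lo, f_hi),
                        config.fs,
                    ) / math.sqrt(len(config.bands)),
                    drift_amplitude=(
                        config.drift_amplitude / len(config.bands)
                    ),
                    seed=np.random.default_rng(
                        derive_seed(config.seed, sid, state, band_name, "obs")
                    ),
                )
                total += sig
                state_entry[band_name] = {
                    "natural_freqs_hz": [float(f) for f in freqs],
                    "couplings": [asdict(c) for c in coups],
                }
            rec = Recording(
                data=total, fs=config.fs, subject_id=sid, group=group,
                state=state,
            )
            p = out_dir / f"{sid}_{state}.{ext}"
            write_recording(rec, p)
            paths[state] = p.name
            sub_entry["states"][state] = state_entry
        ledger["subjects"][sid] = sub_entry
        rows.append(
            dict(
                subject_id=sid, group=group, age=round(age, 1), sex=sex,
                mmse=round(mmse, 1),
                path_sitting=paths.get("sitting", np.nan),
                path_standing=paths.get("standing", np.nan),
            )
        )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.tsv")
    (out_dir / "ground_truth.json").write_text(
        json.dumps(ledger, indent=1, sort_keys=True)
    )
    return manifest, ledger
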