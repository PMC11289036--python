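"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* complex fractional Gaussian noise with a prescribed Hurst exponent
  (exact-covariance circulant embedding), the oracle input for DFA;
* cohorts of spectra sharing a planted low-dimensional basis versus
  spectra drawn from its orthogonal complement, the oracle for the η
  subspace diagnostic — plus a trace-level variant whose participants
  carry construction-known accuracies, drop-in for the full pipeline;
* an agent playing a Whac-A-Mole-style clicking game (targets visible
  650 ms, 350 ms knock-out display after a hit, 120 targets, cursor
  polled every 8–12 ms), producing raw cursor logs whose task accuracy
  is known by construction.

Every generator is deterministic given its spec (which includes the
seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RawTrace, UniformTrace
from .spectral import Spectrum, synthesize

__all__ = [
    "FgnSpec",
    "PlantedCohortSpec",
    "GameSpec",
    "AgentSpec",
    "gen_fgn_complex",
    "gen_planted_cohort",
    "gen_planted_traces",
    "mole_schedule",
    "schedule_hash",
    "gen_game_trace",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise

@dataclass
class FgnSpec:
    """Complex fGn target: Hurst ``H`` in (0,1), length ``N``, scale ``sigma`` px."""

    H: float
    N: int
    dt: float = 20.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.H < 1:
            raise ValueError(f"H must be in (0, 1), got {self.H}")
        if self.N < 16:
            raise ValueError("N must be at least 16")


def _fgn_autocov(H: float, n_lags: int, sigma: float) -> np.ndarray:
    k = np.arange(n_lags + 1, dtype=float)
    return 0.5 * sigma ** 2 * (
        np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )


def gen_fgn_complex(spec: FgnSpec) -> UniformTrace:
    """Complex fGn by circulant embedding (Davies–Harte).

    The target autocovariance is embedded in a circulant matrix whose
    eigenvalues are obtained by FFT; filtering complex white noise
    through its square root yields a proper complex Gaussian vector
    whose real and imaginary parts are *independent* fGn samples with
    exactly the prescribed covariance.  For fGn the embedding is
    nonnegative-definite at size 2N, so the method is exact.
    """
    rng = np.random.default_rng(spec.seed)
    gamma = _fgn_autocov(spec.H, spec.N, spec.sigma)
    row = np.concatenate([gamma, gamma[-2:0:-1]])        # circulant first row, 2N
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)                        # roundoff guard
    M = len(row)
    W = rng.standard_normal(M) + 1j * rng.standard_normal(M)
    Z = np.fft.fft(np.sqrt(lam) * W) / np.sqrt(M)
    z = Z.real[: spec.N] + 1j * Z.imag[: spec.N]
    return UniformTrace(participant_id=f"fgn_H{spec.H}_seed{spec.seed}",
                        z=z, dt=spec.dt, t0=0.0)


# ---------------------------------------------------------------------------
# planted spectral cohorts

@dataclass
class PlantedCohortSpec:
    """Cohorts whose spectra share (or avoid) a planted ``k_true``-dim basis."""

    N: int = 512
    k_true: int = 8
    P_in: int = 40
    P_out: int = 40
    noise_level: float = 0.3
    dt: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_true < self.P_in < self.N:
            raise ValueError("need k_true < P_in < N")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")


def _freqs(N: int, dt: float) -> np.ndarray:
    n = np.arange(-N // 2, N // 2)
    return n / (N * dt * 1e-3)


def _random_orthonormal(rng, N: int, k: int) -> np.ndarray:
    G = rng.standard_normal((N, k)) + 1j * rng.standard_normal((N, k))
    Q, _ = np.linalg.qr(G)
    return Q[:, :k]


def _complex_noise(rng, N: int, level: float) -> np.ndarray:
    # E||e||^2 = level^2 relative to a unit-norm signal
    return level / np.sqrt(2 * N) * (
        rng.standard_normal(N) + 1j * rng.standard_normal(N)
    )


def gen_planted_cohort(spec: PlantedCohortSpec):
    """In-subspace and off-subspace spectrum cohorts plus the true basis.

    In-cohort members are unit-norm random complex combinations of the
    planted orthonormal basis; out-cohort members are unit-norm vectors
    from its orthogonal complement.  Both get additive complex Gaussian
    noise with relative magnitude ``noise_level``.
    """
    rng = np.random.default_rng(spec.seed)
    B = _random_orthonormal(rng, spec.N, spec.k_true)
    f = _freqs(spec.N, spec.dt)

    def as_spectrum(vec: np.ndarray, pid: str) -> Spectrum:
        return Spectrum(participant_id=pid, Z=vec, f=f, N=spec.N, dt=spec.dt)

    in_cohort = []
    for p in range(spec.P_in):
        coef = rng.standard_normal(spec.k_true) + 1j * rng.standard_normal(spec.k_true)
        sig = B @ coef
        sig /= np.linalg.norm(sig)
        in_cohort.append(as_spectrum(sig + _complex_noise(rng, spec.N, spec.noise_level),
                                     f"in_{p:03d}"))
    out_cohort = []
    for p in range(spec.P_out):
        g = rng.standard_normal(spec.N) + 1j * rng.standard_normal(spec.N)
        g -= B @ (B.conj().T @ g)
        g /= np.linalg.norm(g)
        out_cohort.append(as_spectrum(g + _complex_noise(rng, spec.N, spec.noise_level),
                                      f"out_{p:03d}"))
    return in_cohort, out_cohort, B


def gen_planted_traces(spec: PlantedCohortSpec, n_samples: int = 2,
                       accuracy_jitter: float = 0.03) -> list[list[RawTrace]]:
    """Raw-trace cohorts whose accuracy tracks their planted-subspace content.

    Each participant mixes an in-subspace and an orthogonal-complement
    unit spectrum with weight ``w ~ U(0,1)``; accuracy is ``w`` plus a
    small jitter (clipped to [0,1]), so high-accuracy participants carry
    the planted spectral structure.  Spectra are converted to uniform
    20 ms time series via the synthesis relation and returned as raw
    logs, drop-in for the full pipeline.  All samples share one planted
    basis; each has ``P_in + P_out`` participants.
    """
    rng = np.random.default_rng(spec.seed)
    B = _random_orthonormal(rng, spec.N, spec.k_true)
    f = _freqs(spec.N, spec.dt)
    P = spec.P_in + spec.P_out
    samples: list[list[RawTrace]] = []
    for s_idx in range(n_samples):
        sample = []
        for p in range(P):
            w = rng.uniform()
            coef = rng.standard_normal(spec.k_true) + 1j * rng.standard_normal(spec.k_true)
            sig_in = B @ coef
            sig_in /= np.linalg.norm(sig_in)
            g = rng.standard_normal(spec.N) + 1j * rng.standard_normal(spec.N)
            g -= B @ (B.conj().T @ g)
            g /= np.linalg.norm(g)
            vec = (np.sqrt(w) * sig_in + np.sqrt(1 - w) * g
                   + _complex_noise(rng, spec.N, spec.noise_level))
            pid = f"s{s_idx + 1}_p{p:03d}"
            z = synthesize(Spectrum(participant_id=pid, Z=vec, f=f,
                                    N=spec.N, dt=spec.dt))
            acc = float(np.clip(w + rng.normal(0, accuracy_jitter), 0.0, 1.0))
            t = spec.dt * np.arange(spec.N)
            sample.append(RawTrace(participant_id=pid, t=t,
                                   x=z.real, y=z.imag, accuracy=acc))
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# Whac-A-Mole gameplay

@dataclass
class GameSpec:
    """Clicking-game parameters: target timing, count, layout, polling."""

    n_moles: int = 120
    visible_ms: float = 650.0
    stunned_ms: float = 350.0
    n_hills: int = 9
    screen_px: tuple = (800, 600)
    hit_radius_px: float = 30.0
    poll_ms_range: tuple = (8.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.visible_ms <= 0 or self.stunned_ms <= 0:
            raise ValueError("durations must be positive")
        if self.n_hills < 2:
            raise ValueError("need at least 2 hills")


@dataclass
class AgentSpec:
    """Synthetic player: noisy proportional approach with a speed cap.

    Not a model of human motor control — it exists to produce cursor
    logs whose task accuracy is known by construction.  ``reactive``
    agents chase the visible target after ``reaction_ms``; ``camper``
    agents park on one hill and click on a fixed cadence.
    """

    reaction_ms: float = 250.0
    gain_per_ms: float = 0.012
    speed_cap_px_s: float = 1500.0
    motor_noise_px: float = 1.5
    click_jitter_px: float = 3.0
    click_radius_px: float = 15.0
    click_cooldown_ms: float = 180.0
    strategy: str = "reactive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reaction_ms < 0:
            raise ValueError("reaction_ms must be nonnegative")
        if self.speed_cap_px_s <= 0:
            raise ValueError("speed cap must be positive")
        if self.strategy not in ("reactive", "camper"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def hill_positions(game: GameSpec) -> np.ndarray:
    """Hill centers on a near-square grid inside the screen, (n_hills, 2) px."""
    n_cols = int(np.ceil(np.sqrt(game.n_hills)))
    n_rows = int(np.ceil(game.n_hills / n_cols))
    w, h = game.screen_px
    xs = np.linspace(0.15 * w, 0.85 * w, n_cols)
    ys = np.linspace(0.15 * h, 0.85 * h, n_rows)
    pos = [(x, y) for y in ys for x in xs]
    return np.array(pos[: game.n_hills])


def mole_schedule(game: GameSpec) -> np.ndarray:
    """Pseudo-random hill sequence, uniform over hills excluding the current
    one; fixed by the game seed so every agent sees the same sequence."""
    rng = np.random.default_rng(game.seed)
    seq = np.empty(game.n_moles, dtype=int)
    current = -1
    for i in range(game.n_moles):
        choices = [h for h in range(game.n_hills) if h != current]
        current = int(rng.choice(choices))
        seq[i] = current
    return seq


def schedule_hash(game: GameSpec) -> str:
    return hashlib.sha256(mole_schedule(game).tobytes()).hexdigest()


def gen_game_trace(game: GameSpec, agent: AgentSpec) -> tuple[RawTrace, float]:
    """Simulate one agent playing one game; returns (raw log, accuracy).

    Event loop: the agent polls every 8–12 ms (browser-like jitter).
    After its reaction latency it steers toward the visible target with
    a noisy proportional controller capped at ``speed_cap_px_s``, and
    clicks (with spatial jitter) once within ``click_radius_px``.  A
    target hit inside ``hit_radius_px`` while visible counts; accuracy
    is hits / n_moles.
    """
    rng = np.random.default_rng(agent.seed)
    hills = hill_positions(game)
    seq = mole_schedule(game)

    pos = np.array(game.screen_px, dtype=float) / 2.0
    camp_hill = hills[np.bincount(seq, minlength=game.n_hills).argmax()]

    t = 0.0
    mole_idx = 0
    appear_t = 0.0
    mole_hit = False
    hits = 0
    last_click_t = -np.inf

    times, xs, ys, clicks = [], [], [], []

    while mole_idx < game.n_moles:
        mole_pos = hills[seq[mole_idx]]
        visible = (not mole_hit) and (t - appear_t) < game.visible_ms

        if agent.strategy == "camper":
            target, may_click = camp_hill, True
        else:
            aware = visible and (t - appear_t) >= agent.reaction_ms
            target = mole_pos if aware else None
            may_click = aware

        dt_poll = rng.uniform(*game.poll_ms_range)
        if target is not None:
            # proportional step, clamped so it never overshoots the target
            frac = min(agent.gain_per_ms * dt_poll, 1.0)
            step = frac * (target - pos)
            max_step = agent.speed_cap_px_s * dt_poll * 1e-3
            norm = np.hypot(*step)
            if norm > max_step:
                step *= max_step / norm
            pos = pos + step + rng.normal(0, agent.motor_noise_px, 2)
        else:
            pos = pos + rng.normal(0, agent.motor_noise_px, 2)

        if (may_click and t - last_click_t >= agent.click_cooldown_ms):
            aim = target if target is not None else pos
            if np.hypot(*(aim - pos)) <= agent.click_radius_px:
                click_at = pos + rng.normal(0, agent.click_jitter_px, 2)
                clicks.append((t, float(click_at[0]), float(click_at[1])))
                last_click_t = t
                if (visible and not mole_hit
                        and np.hypot(*(click_at - mole_pos)) <= game.hit_radius_px):
                    mole_hit = True
                    hits += 1
                    appear_t = t  # stunned display starts now

        times.append(t)
        xs.append(float(pos[0]))
        ys.append(float(pos[1]))

        # advance the mole state machine
        dwell = game.stunned_ms if mole_hit else game.visible_ms
        if t - appear_t >= dwell:
            mole_idx += 1
            appear_t = t
            mole_hit = False
        t += dt_poll

    accuracy = hits / game.n_moles
    trace = RawTrace(
        participant_id=f"agent_r{agent.reaction_ms:g}_s{agent.seed}",
        t=np.array(times), x=np.array(xs), y=np.array(ys),
        clicks=clicks, accuracy=accuracy,
    )
    return trace, accuracy
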