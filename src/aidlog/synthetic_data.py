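"""Ground-truthed synthetic datalog generator.

The generator emulates the statistical structure a manufacturer datalog
export is assumed to have, so that every downstream analysis stage can be
exercised and its recovery of *planted* signal measured without any real
(proprietary) data:

* **Audiogram archetypes.**  Each wearer's audiogram is a multivariate
  normal draw around one of a small set of archetype shapes (a sloping
  presbyacusis-like loss, a flat moderate loss, and a noise-induced
  3--6 kHz notch with good low-frequency hearing), clipped to the clinical
  range and rounded to 5-dB audiometric steps.  Per-visit test--retest
  noise is added on top of the wearer's base audiogram.
* **Acoustic-demand profiles.**  The 12-bin input-SPL histogram is a
  Dirichlet draw around one of a few latent demand profiles (quiet /
  moderate / loud).  Style--profile associations can be planted with a
  prescribed lift, giving downstream subgroup discovery a known target.
* **Directionality link.**  For BTE styles the fraction of time in
  directional mode follows a linear link to the histogram's mean input SPL
  plus Gaussian noise.  A configurable fraction of BTEa snapshots is
  *decoupled* from the link (directionality stuck or random) by at least
  5 link noise-sd, providing ground-truth outliers for the GP anomaly
  detector.
* **Loan devices.**  A fraction of multi-visit BTE devices switches wearer
  once; the post-switch audiogram is constrained so the measured
  improvement is >= 15 dB at >= 3 frequencies with the visit gap strictly
  inside (7, 60) days, i.e. detectable by the loan rule.
* **Dirt.**  Short-usage visits (days since last visit <= 7), low-usage
  records whose stored proportions sum below 0.9, two-significant-figure
  quantization of all stored proportions, and audiogram missing-value
  patterns, so the cleaning rules have real work to do.

Everything is driven by one seeded :class:`numpy.random.Generator`; a fixed
seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datalog_model import (
    ACOUSTIC_COLUMNS,
    AUDIOGRAM_COLUMNS,
    AUDIOGRAM_FREQUENCIES,
    BTE_STYLES,
    COLUMNS,
    ConfigError,
    Dataset,
    Audiogram,
    InputSPLHistogram,
    SPL_BIN_REPRESENTATIVES,
    SPL_COLUMNS,
    STYLES,
    _coerce_dtypes,
)

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "simulate_dataset",
    "simulate_audiogram",
    "simulate_spl_histogram",
    "round_2sf",
]


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------


def round_2sf(x: np.ndarray | float) -> np.ndarray:
    """Round to two significant figures, half to even (IEEE banker's rounding).

    Zero maps to zero.  This mirrors the datalog's storage precision for
    time proportions.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = (x != 0) & np.isfinite(x)
    if nz.any():
        mag = np.floor(np.log10(np.abs(x[nz]))).astype(int)
        scale = 10.0 ** (mag - 1)
        out[nz] = np.round(x[nz] / scale) * scale
    out[~np.isfinite(x)] = x[~np.isfinite(x)]
    return out if out.ndim else float(out)


def _round_5dB(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float) / 5.0) * 5.0


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeSpec:
    """An audiogram shape archetype.

    ``mean`` is the 8-frequency mean shape in dB HL, ``scale`` the per-frequency
    standard deviation of the (diagonal) between-wearer covariance, ``weight``
    the mixing proportion.
    """

    name: str
    mean: tuple[float, ...]
    scale: float
    weight: float


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic datalog generator.

    The defaults (see :func:`default_config`) are the generator's declared
    study conditions; rates are fractions in [0, 1].
    """

    n_devices: int = 5000
    visits_min: int = 1
    visits_max: int = 6
    style_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "CIC": 0.10,
            "HalfShell": 0.07,
            "ITE": 0.08,
            "ITC": 0.08,
            "BTEa": 0.55,
            "BTEb": 0.12,
        }
    )
    audiogram_archetypes: tuple[ArchetypeSpec, ...] = (
        ArchetypeSpec("presbyacusis", (20, 25, 35, 45, 50, 55, 60, 65), 6.0, 0.55),
        ArchetypeSpec("flat", (30, 30, 32, 35, 35, 38, 40, 40), 6.0, 0.30),
        ArchetypeSpec("nihl_notch", (5, 10, 15, 25, 45, 50, 35, 15), 5.0, 0.15),
    )
    #: Latent acoustic-demand profiles: name -> mean simplex over the 12 bins.
    spl_profiles: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "quiet": (0.30, 0.20, 0.14, 0.10, 0.08, 0.06, 0.045, 0.030, 0.020, 0.012, 0.008, 0.005),
            "moderate": (0.02, 0.03, 0.05, 0.08, 0.12, 0.16, 0.16, 0.13, 0.10, 0.07, 0.05, 0.03),
            "loud": (0.01, 0.015, 0.02, 0.03, 0.05, 0.07, 0.10, 0.13, 0.16, 0.17, 0.14, 0.105),
        }
    )
    #: Base profile mixing probabilities (per wearer), before planted lifts.
    profile_probs: Mapping[str, float] = field(
        default_factory=lambda: {"quiet": 0.35, "moderate": 0.35, "loud": 0.30}
    )
    #: Dirichlet concentration multiplier: histogram ~ Dir(kappa * profile mean).
    spl_concentration: float = 60.0
    #: Planted (style, profile, lift) associations: P(profile|style) is raised
    #: so that its lift over the realized population marginal equals ``lift``.
    planted_associations: tuple[tuple[str, str, float], ...] = (("CIC", "loud", 1.5),)
    #: Optional hard override: style -> full profile distribution.  When given,
    #: planted_associations and profile_probs are ignored for that style.
    style_profile_probs: Mapping[str, Mapping[str, float]] | None = None
    loan_rate: float = 0.08
    anomaly_rate: float = 0.01
    #: Audiogram missing-value patterns: tuple of missing frequencies -> prob.
    #: Remaining mass goes to the all-present pattern.
    missingness: Mapping[tuple[int, ...], float] = field(
        default_factory=lambda: {
            (8000,): 0.11,
            (3000, 6000): 0.08,
            (3000,): 0.05,
            (6000,): 0.04,
            tuple(AUDIOGRAM_FREQUENCIES): 0.0043,
        }
    )
    #: fraction_directional = intercept + slope*(mean_spl - 65) + N(0, noise_sd),
    #: clipped to [0, 1]; applies to BTE styles (in-ear styles have no
    #: directional microphone and log 0).
    directionality_link: tuple[float, float, float] = (0.015, 0.5, 0.05)
    #: Gain reductions (dB): quiet couples to low-SPL occupancy (bins <= 55 dB),
    #: noise couples to high-SPL occupancy (bins >= 70 dB):
    #: (quiet_intercept, quiet_slope, noise_intercept, noise_slope, noise_sd).
    gain_reduction_link: tuple[float, float, float, float, float] = (0.5, 6.0, 1.0, 5.0, 0.8)
    #: Per-visit audiogram test-retest noise sd (dB).
    retest_sd: float = 2.5
    #: Fraction of visits with <= 7 days since the last visit (short usage).
    short_use_rate: float = 0.06
    #: Fraction of records stored with proportion sums < 0.9 (low usage).
    low_sum_rate: float = 0.02
    quantize_2sf: bool = True
    seed: int = 20180531

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n_devices < 0:
            raise ConfigError("n_devices must be >= 0")
        if not (1 <= self.visits_min <= self.visits_max):
            raise ConfigError("need 1 <= visits_min <= visits_max")
        if set(self.style_probs) != set(STYLES):
            raise ConfigError("style_probs must cover exactly the six styles")
        sp = np.array([self.style_probs[s] for s in STYLES])
        if (sp < 0).any() or abs(sp.sum() - 1) > 1e-9:
            raise ConfigError("style_probs must be a probability vector")
        w = np.array([a.weight for a in self.audiogram_archetypes])
        if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ConfigError("archetype weights must sum to 1")
        for rate in (self.loan_rate, self.anomaly_rate, self.short_use_rate, self.low_sum_rate):
            if not 0 <= rate <= 1:
                raise ConfigError("rates must lie in [0, 1]")
        bte_mass = sum(self.style_probs[s] for s in BTE_STYLES)
        if self.loan_rate > 0 and bte_mass == 0:
            raise ConfigError("loan_rate > 0 requires BTE style mass")
        if self.anomaly_rate > 0 and self.style_probs["BTEa"] == 0:
            raise ConfigError("anomaly_rate > 0 requires BTEa style mass")
        pp = np.array([self.profile_probs[k] for k in self.spl_profiles])
        if (pp < 0).any() or abs(pp.sum() - 1) > 1e-9:
            raise ConfigError("profile_probs must be a probability vector over spl_profiles")
        for _, prof, lift in self.planted_associations:
            if prof not in self.spl_profiles or lift <= 0:
                raise ConfigError("planted association references unknown profile or lift <= 0")
        mtot = sum(self.missingness.values())
        if mtot > 1 or any(p < 0 for p in self.missingness.values()):
            raise ConfigError("missingness probabilities must be >= 0 and sum to <= 1")


def default_config(**overrides) -> SimulationConfig:
    """The default study conditions, optionally with field overrides."""
    return replace(SimulationConfig(), **overrides)


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted labels emitted alongside a simulated dataset.

    ``devices``: one row per device (style, loan flag, switch session,
    wearer archetype, demand profile).  ``snapshots``: one row per record
    (outlier flag, representative-use flag, active profile).
    ``association_lifts``: realized style--profile lifts for every planted
    association.
    """

    devices: pd.DataFrame
    snapshots: pd.DataFrame
    association_lifts: list[dict]

    def __len__(self) -> int:
        return len(self.snapshots)


# ---------------------------------------------------------------------------
# Elementary draws
# ---------------------------------------------------------------------------


def simulate_audiogram(archetype: ArchetypeSpec, rng: np.random.Generator) -> Audiogram:
    """Draw one wearer audiogram: normal around the archetype mean, clipped to
    [-10, 120] dB HL and rounded to 5-dB steps."""
    vals = _draw_audiogram_bases(
        np.asarray(archetype.mean, dtype=float)[None, :], archetype.scale, rng
    )[0]
    return Audiogram(tuple(vals))


def _draw_audiogram_bases(means: np.ndarray, scale, rng: np.random.Generator) -> np.ndarray:
    draw = means + np.asarray(scale) * rng.standard_normal(means.shape)
    return _round_5dB(np.clip(draw, -10, 120))


def simulate_spl_histogram(
    profile: Sequence[float], rng: np.random.Generator, concentration: float = 60.0
) -> InputSPLHistogram:
    """Draw one input-SPL histogram from a Dirichlet around ``profile``.

    The draw sums to exactly 1; two-significant-figure quantization, when
    wanted, is applied by the dataset-level simulator, not here.
    """
    conc = np.asarray(profile, dtype=float) * concentration
    if (conc <= 0).any():
        raise ConfigError("profile concentration must be strictly positive")
    return InputSPLHistogram(tuple(rng.dirichlet(conc)))


def _dirichlet_rows(conc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise Dirichlet draws via normalized gammas (vectorized)."""
    g = rng.standard_gamma(conc)
    return g / g.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Planted style-profile association solver
# ---------------------------------------------------------------------------


def _style_profile_matrix(config: SimulationConfig) -> tuple[np.ndarray, list[dict]]:
    """Per-style profile distributions realizing the planted lifts.

    Returns ``(P, lifts)`` where ``P[i, j] = P(profile j | style i)`` and
    ``lifts`` records the realized lift of each planted association against
    the population marginal.  Solved by fixed-point iteration because a
    planted boost changes the marginal it is defined against.
    """
    profiles = list(config.spl_profiles)
    base = np.array([config.profile_probs[p] for p in profiles])
    sp = np.array([config.style_probs[s] for s in STYLES])
    P = np.tile(base, (len(STYLES), 1))

    if config.style_profile_probs is not None:
        for s, dist in config.style_profile_probs.items():
            row = np.array([dist.get(p, 0.0) for p in profiles])
            if abs(row.sum() - 1) > 1e-9 or (row < 0).any():
                raise ConfigError(f"style_profile_probs[{s!r}] is not a distribution")
            P[STYLES.index(s)] = row
        return P, []

    planted = {}
    for s, prof, lift in config.planted_associations:
        if s in planted:
            raise ConfigError("at most one planted association per style")
        planted[s] = (profiles.index(prof), lift)

    for _ in range(200):
        marginal = sp @ P
        newP = np.tile(base, (len(STYLES), 1))
        for s, (j, lift) in planted.items():
            i = STYLES.index(s)
            target = lift * marginal[j]
            if target >= 1:
                raise ConfigError(f"planted lift {lift} on {s}/{profiles[j]} is infeasible")
            row = base.copy()
            row *= (1 - target) / (1 - base[j])
            row[j] = target
            newP[i] = row
        if np.allclose(newP, P, atol=1e-12):
            P = newP
            break
        P = newP

    marginal = sp @ P
    lifts = [
        {
            "style": s,
            "profile": profiles[j],
            "nominal_lift": lift,
            "realized_lift": float(P[STYLES.index(s), j] / marginal[j]),
        }
        for s, (j, lift) in planted.items()
    ]
    return P, lifts


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate a datalog dataset plus its ground truth.

    Deterministic given ``config.seed``.  See the module docstring for the
    generative model; notable guarantees:

    * loan devices exhibit a measured improvement of >= 15 dB at >= 3
      frequencies at the switch visit, with 7 < days-since-last-visit < 60;
    * planted outliers deviate from the directionality link's implied
      conditional mean of mean-input-SPL given directionality by at least
      5 link noise-sd (in dB);
    * stored proportions are quantized to two significant figures when
      ``quantize_2sf`` is set; planted low-usage rows have proportion sums
      strictly below 0.9.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = list(config.spl_profiles)
    profile_means = np.array([config.spl_profiles[p] for p in profiles], dtype=float)
    P_style_profile, lifts = _style_profile_matrix(config)

    n = config.n_devices
    if n == 0:
        empty = Dataset(_coerce_dtypes(pd.DataFrame(columns=list(COLUMNS))), "synthetic")
        truth = GroundTruth(
            devices=pd.DataFrame(
                columns=["device_id", "style", "archetype", "profile", "loan", "switch_session_seq", "n_visits"]
            ),
            snapshots=pd.DataFrame(
                columns=["device_id", "session_seq", "visit_index", "profile", "outlier", "representative"]
            ),
            association_lifts=lifts,
        )
        return empty, truth

    # --- device-level draws ------------------------------------------------
    style_idx = rng.choice(len(STYLES), size=n, p=[config.style_probs[s] for s in STYLES])
    styles = np.array(STYLES, dtype=object)[style_idx]
    visits = rng.integers(config.visits_min, config.visits_max + 1, size=n)
    arch_w = np.array([a.weight for a in config.audiogram_archetypes])
    arch_idx = rng.choice(len(config.audiogram_archetypes), size=n, p=arch_w)
    profile_idx_dev = np.array(
        [rng.choice(len(profiles), p=P_style_profile[i]) for i in style_idx]
    )

    is_bte = np.isin(styles, BTE_STYLES)
    eligible = is_bte & (visits >= 2)
    loan = eligible & (rng.random(n) < config.loan_rate)
    switch_visit = np.full(n, -1)
    switch_visit[loan] = np.array(
        [rng.integers(1, v) for v in visits[loan]]
    )  # visit index (0-based) at which the new wearer appears

    device_ids = np.array([f"D{i:07d}" for i in range(n)], dtype=object)

    # --- row scaffolding ---------------------------------------------------
    m = int(visits.sum())
    dev_of_row = np.repeat(np.arange(n), visits)
    visit_index = np.concatenate([np.arange(v) for v in visits])

    # days since last visit: short-usage mass at <= 7 days, else 8..180;
    # loan switch visits forced strictly inside the (7, 60) day window.
    days = rng.integers(8, 181, size=m)
    short = rng.random(m) < config.short_use_rate
    days[short] = rng.integers(0, 8, size=int(short.sum()))
    is_switch_row = loan[dev_of_row] & (visit_index == switch_visit[dev_of_row])
    days[is_switch_row] = rng.integers(8, 60, size=int(is_switch_row.sum()))

    # --- wearer profiles and histograms ------------------------------------
    # Loan devices change wearer at the switch: new demand profile too.
    profile_idx_dev2 = profile_idx_dev.copy()
    for i in np.flatnonzero(loan):
        profile_idx_dev2[i] = rng.choice(len(profiles), p=P_style_profile[style_idx[i]])
    after_switch = loan[dev_of_row] & (visit_index >= switch_visit[dev_of_row])
    profile_of_row = np.where(
        after_switch, profile_idx_dev2[dev_of_row], profile_idx_dev[dev_of_row]
    )

    conc = profile_means[profile_of_row] * config.spl_concentration
    hist_true = _dirichlet_rows(conc, rng)
    y_true = hist_true @ SPL_BIN_REPRESENTATIVES

    # --- directionality link and planted outliers --------------------------
    slope, intercept, noise_sd = config.directionality_link
    frac_dir = np.zeros(m)
    bte_rows = is_bte[dev_of_row]
    frac_dir[bte_rows] = intercept + slope * (y_true[bte_rows] - 65.0) + rng.normal(
        0, noise_sd, size=int(bte_rows.sum())
    )
    frac_dir = np.clip(frac_dir, 0.0, 1.0)

    btea_rows = np.flatnonzero(styles[dev_of_row] == "BTEa")
    outlier = np.zeros(m, dtype=bool)
    if btea_rows.size and config.anomaly_rate > 0:
        chosen = btea_rows[rng.random(btea_rows.size) < config.anomaly_rate]
        outlier[chosen] = True
        sd_y = noise_sd / slope  # link noise expressed in dB of mean input SPL
        for r in chosen:
            accepted = False
            for _ in range(200):
                donor = btea_rows[rng.integers(btea_rows.size)]
                x_cand = float(
                    np.clip(
                        intercept + slope * (y_true[donor] - 65.0) + rng.normal(0, noise_sd),
                        0.0,
                        1.0,
                    )
                )
                implied_y = 65.0 + (x_cand - intercept) / slope
                if abs(y_true[r] - implied_y) >= 5.0 * sd_y:
                    frac_dir[r] = x_cand
                    accepted = True
                    break
            if not accepted:
                # construct directly: displace along the link by 6 noise-sd
                sign = 1.0 if y_true[r] < 65.0 else -1.0
                frac_dir[r] = float(
                    np.clip(intercept + slope * (y_true[r] - 65.0 + sign * 6 * sd_y), 0.0, 1.0)
                )
    frac_dir = np.round(frac_dir, 3)

    # --- acoustic classes, gain reductions, mean SPL ------------------------
    low_occ = hist_true[:, :4].sum(axis=1)  # bins up to 55 dB SPL
    high_occ = hist_true[:, 7:].sum(axis=1)  # bins from 70 dB SPL
    ac_mean = np.stack(
        [0.20 + 0.55 * low_occ, 0.12 + 0.50 * high_occ, np.zeros(m)], axis=1
    )
    ac_mean[:, 2] = 1.0 - ac_mean[:, 0] - ac_mean[:, 1]
    ac_true = _dirichlet_rows(ac_mean * 50.0, rng)

    qi, qs, ni, ns, gr_sd = config.gain_reduction_link
    gr_quiet = np.clip(qi + qs * low_occ + rng.normal(0, gr_sd, m), 0, None)
    gr_noise = np.clip(ni + ns * high_occ + rng.normal(0, gr_sd, m), 0, None)
    gr_quiet = np.round(gr_quiet, 1)
    gr_noise = np.round(gr_noise, 1)
    mean_spl_logged = np.round(y_true + rng.normal(0, 0.3, m), 1)

    # --- low-usage scaling and quantization ---------------------------------
    low_sum = rng.random(m) < config.low_sum_rate
    scale_f = np.ones(m)
    scale_f[low_sum] = rng.uniform(0.40, 0.85, size=int(low_sum.sum()))
    hist_stored = hist_true * scale_f[:, None]
    ac_stored = ac_true * scale_f[:, None]
    if config.quantize_2sf:
        hist_stored = round_2sf(hist_stored)
        ac_stored = round_2sf(ac_stored)

    # --- audiograms ---------------------------------------------------------
    arch_means = np.array([a.mean for a in config.audiogram_archetypes], dtype=float)
    arch_scales = np.array([a.scale for a in config.audiogram_archetypes])
    base_A = _draw_audiogram_bases(
        arch_means[arch_idx], arch_scales[arch_idx][:, None], rng
    )
    base_of_row = base_A[dev_of_row].copy()
    measured = _round_5dB(
        np.clip(base_of_row + rng.normal(0, config.retest_sd, size=(m, 8)), -10, 120)
    )

    # loan devices: rejection-sample the new wearer so the measured switch
    # pair satisfies the detection rule (>= 15 dB improvement at >= 3 freqs).
    row_start = np.concatenate([[0], np.cumsum(visits)[:-1]])
    for i in np.flatnonzero(loan):
        sw = switch_visit[i]
        prev_row = row_start[i] + sw - 1
        rows_after = row_start[i] + np.arange(sw, visits[i])
        prev_meas = measured[prev_row]
        ok = False
        for attempt in range(500):
            j = rng.choice(len(config.audiogram_archetypes), p=arch_w)
            base_B = _draw_audiogram_bases(arch_means[j][None, :], arch_scales[j], rng)[0]
            meas_B = _round_5dB(
                np.clip(
                    base_B + rng.normal(0, config.retest_sd, size=(len(rows_after), 8)),
                    -10,
                    120,
                )
            )
            if ((prev_meas - meas_B[0]) >= 15).sum() >= 3:
                ok = True
                break
        if not ok:  # wearer A near the floor: construct an improved audiogram
            base_B = np.clip(base_A[i] - 25.0, -10, 120)
            meas_B = _round_5dB(
                np.clip(
                    base_B + rng.normal(0, config.retest_sd, size=(len(rows_after), 8)),
                    -10,
                    120,
                )
            )
            worst = np.argsort(prev_meas - meas_B[0])
            meas_B[0, worst[:5]] = np.maximum(prev_meas[worst[:5]] - 20.0, -10.0)
        measured[rows_after] = meas_B

    # --- audiogram missingness (loan devices exempt) ------------------------
    patterns = [()] + list(config.missingness)
    probs = np.array([1 - sum(config.missingness.values())] + list(config.missingness.values()))
    pat_idx = rng.choice(len(patterns), size=m, p=probs)
    pat_idx[loan[dev_of_row]] = 0
    freq_pos = {f: k for k, f in enumerate(AUDIOGRAM_FREQUENCIES)}
    for k, pat in enumerate(patterns):
        if not pat:
            continue
        rows = pat_idx == k
        for f in pat:
            measured[rows, freq_pos[f]] = np.nan

    # --- global session chronology ------------------------------------------
    start = rng.uniform(0, 3650, size=n)
    t = start[dev_of_row] + np.concatenate(
        [np.cumsum(days[row_start[i] : row_start[i] + visits[i]]) for i in range(n)]
    ).astype(float)
    t += rng.uniform(0, 0.5, size=m)  # break ties across devices
    order = np.argsort(t, kind="stable")
    session_seq = np.empty(m, dtype=int)
    session_seq[order] = np.arange(1, m + 1)

    # --- assemble -----------------------------------------------------------
    data = {
        "device_id": device_ids[dev_of_row],
        "session_seq": session_seq,
        "days_since_last_visit": days,
        "style": styles[dev_of_row],
    }
    for k, c in enumerate(AUDIOGRAM_COLUMNS):
        data[c] = measured[:, k]
    for k, c in enumerate(SPL_COLUMNS):
        data[c] = hist_stored[:, k]
    for k, c in enumerate(ACOUSTIC_COLUMNS):
        data[c] = ac_stored[:, k]
    data["gain_reduction_noise"] = gr_noise
    data["gain_reduction_quiet"] = gr_quiet
    data["fraction_directional"] = frac_dir
    data["mean_input_spl"] = mean_spl_logged
    frame = _coerce_dtypes(pd.DataFrame(data, columns=list(COLUMNS)))
    dataset = Dataset(frame, provenance=f"synthetic(seed={config.seed})")

    representative = (
        (days > 7)
        & (np.nansum(hist_stored, axis=1) >= 0.9)
        & (np.nansum(ac_stored, axis=1) >= 0.9)
    )
    switch_seq = np.full(n, np.nan)
    for i in np.flatnonzero(loan):
        switch_seq[i] = session_seq[row_start[i] + switch_visit[i]]
    truth = GroundTruth(
        devices=pd.DataFrame(
            {
                "device_id": device_ids,
                "style": styles,
                "archetype": np.array(
                    [config.audiogram_archetypes[k].name for k in arch_idx], dtype=object
                ),
                "profile": np.array([profiles[k] for k in profile_idx_dev], dtype=object),
                "loan": loan,
                "switch_session_seq": pd.array(switch_seq, dtype="Int64"),
                "n_visits": visits,
            }
        ),
        snapshots=pd.DataFrame(
            {
                "device_id": device_ids[dev_of_row],
                "session_seq": session_seq,
                "visit_index": visit_index,
                "profile": np.array([profiles[k] for k in profile_of_row], dtype=object),
                "outlier": outlier,
                "representative": representative,
            }
        ),
        association_lifts=lifts,
    )
    return dataset, truth
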