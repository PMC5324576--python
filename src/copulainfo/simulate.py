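"""Seeded generators for every simulated system used to validate the estimators.

Each generator is bit-reproducible given its parameters and seed, and emulates
one of the study conditions the estimators are designed for: correlated
Gaussian stimulus features, stimulus-modulated multivariate Gaussian
responses, von Mises phase / chi-square amplitude spectral classes,
event-related trial grids with planted effects, autocorrelated continuous
lagged-dependence pairs, and outlier corruption.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "gen_bivariate_gaussian",
    "gen_trivariate_gaussian",
    "gen_correlated_feature_responses",
    "gen_spectral_classes",
    "gen_event_related",
    "gen_continuous_lagged",
    "corrupt_outliers",
]


def gen_bivariate_gaussian(r: float, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """N samples from a bivariate Gaussian with population correlation ``r``.

    The analytic MI of the pair is -0.5*log2(1 - r^2) bits.
    """
    if not -1 < r < 1:
        raise ValueError("correlation must satisfy |r| < 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = r * z[:, 0] + np.sqrt(1.0 - r**2) * z[:, 1]
    return x, y


def gen_trivariate_gaussian(
    r_stim: float, r_resp: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """1-D stimulus correlated ``r_stim`` with each component of a 2-D response.

    The two response components are themselves correlated ``r_resp``.  Raises
    when the implied covariance matrix is not positive definite.
    """
    cov = np.array(
        [
            [1.0, r_stim, r_stim],
            [r_stim, 1.0, r_resp],
            [r_stim, r_resp, 1.0],
        ]
    )
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"r_stim={r_stim}, r_resp={r_resp} imply a non-positive-definite covariance"
        ) from None
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 3)) @ chol.T
    return z[:, 0], z[:, 1:]


def gen_correlated_feature_responses(
    n: int, noise_sd: float = 1.0, seed: int = 0, covariance: float = 0.6
) -> dict[str, np.ndarray]:
    """Two correlated unit-variance Gaussian stimulus features plus two responses.

    ``stim1`` and ``stim2`` have covariance 0.6 (the default study condition);
    ``resp_single`` = stim1 + noise encodes only feature 1 (its apparent MI
    with feature 2 is inherited entirely from the feature correlation, so
    CMI(resp_single; stim2 | stim1) = 0 at the population level), while
    ``resp_sum`` = stim1 + stim2 + noise genuinely encodes both features.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, covariance], [covariance, 1.0]])
    stim = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    noise = rng.standard_normal(n) * noise_sd
    return {
        "stim1": stim[:, 0],
        "stim2": stim[:, 1],
        "resp_single": stim[:, 0] + noise,
        "resp_sum": stim[:, 0] + stim[:, 1] + noise,
    }


def gen_spectral_classes(
    mode: str,
    n: int,
    seed: int,
    kappa: float = 2.0,
    phase_means: tuple[float, float] = (0.0, np.pi),
    dof: float = 3.0,
    dof_by_class: tuple[float, float] = (2.0, 8.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class complex spectral coefficients with phase- or amplitude-coding.

    ``mode='phase'``: phase drawn from a von Mises distribution with a
    class-specific mean (``phase_means``) and shared concentration ``kappa``;
    amplitude from a chi-square with shared ``dof``.  ``mode='amplitude'``:
    shared von Mises phase, chi-square amplitude with class-specific
    ``dof_by_class``.  Returns an (N, 2) real/imaginary matrix and labels.

    The defaults give a clear but non-saturated effect in the modulated
    channel and none in the other, producing the double dissociation between
    the amplitude and direction information channels.
    """
    if mode not in ("phase", "amplitude"):
        raise ValueError(f"mode must be 'phase' or 'amplitude', got {mode!r}")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    if mode == "phase":
        mu = np.asarray(phase_means)[labels]
        theta = rng.vonmises(mu, kappa)
        amp = rng.chisquare(dof, size=n)
    else:
        theta = rng.vonmises(0.0, kappa, size=n)
        amp = rng.chisquare(np.asarray(dof_by_class)[labels])
    z = np.column_stack([amp * np.cos(theta), amp * np.sin(theta)])
    return z, labels


def gen_event_related(
    n_trials: int,
    n_time: int,
    n_chan: int,
    seed: int,
    effect_channel: int | None = None,
    effect_times: tuple[int, ...] = (),
    effect_size: float = 0.0,
    stimulus: str = "classes",
    time_profile: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-related trial grid: unit Gaussian noise with an optional planted effect.

    Returns (data, y) with data of shape (n_trials, n_chan, n_time).  With
    ``stimulus='classes'`` y is a balanced random binary label vector and the
    planted effect is a class-mean shift of ``effect_size`` at the specified
    (channel, time) cells; with ``stimulus='feature'`` y is a standard-normal
    trial feature modulating those cells linearly with gain ``effect_size``.
    ``time_profile`` scales the effect across ``effect_times`` -- a profile
    crossing zero plants the sign-flipping modulation whose raw-value MI time
    course dips to zero at the crossing (removed by derivative augmentation).
    """
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_chan, n_time))
    if stimulus == "classes":
        y = np.zeros(n_trials, dtype=int)
        y[rng.permutation(n_trials)[: n_trials // 2]] = 1
        drive = 2.0 * (y - 0.5)
    elif stimulus == "feature":
        y = rng.standard_normal(n_trials)
        drive = y
    else:
        raise ValueError(f"unknown stimulus kind {stimulus!r}")
    if effect_size != 0.0 and effect_times:
        if effect_channel is None or not 0 <= effect_channel < n_chan:
            raise ValueError("effect_channel must index a channel")
        profile = (
            np.ones(len(effect_times))
            if time_profile is None
            else np.asarray(time_profile, dtype=float)
        )
        if profile.shape[0] != len(effect_times):
            raise ValueError("time_profile must match effect_times in length")
        for t, w in zip(effect_times, profile):
            data[:, effect_channel, t] += effect_size * w * drive
    return data, y


def gen_continuous_lagged(
    n_samples: int,
    lag: int,
    gain: float,
    seed: int,
    cutoff: float = 0.1,
    order: int = 3,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelated feature series driving a response ``lag`` samples later.

    The feature is low-pass-filtered white noise (Butterworth of the given
    ``order``, ``cutoff`` as a fraction of Nyquist, zero-phase), standardized;
    the response is ``gain`` times the feature ``lag`` samples earlier plus
    filtered noise.  The autocorrelation makes naive sample permutation an
    invalid null -- chance coincidences extend over neighbouring samples -- so
    this generator is the test bed for the block/circular permutation schemes.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    rng = np.random.default_rng(seed)
    b, a = signal.butter(order, cutoff)

    def lowpass_noise(m: int) -> np.ndarray:
        x = signal.filtfilt(b, a, rng.standard_normal(m))
        return (x - x.mean()) / x.std()

    f_full = lowpass_noise(n_samples + lag)
    feature = f_full[lag:]
    response = gain * f_full[:n_samples] + noise_sd * lowpass_noise(n_samples)
    return feature, response


def corrupt_outliers(
    data: np.ndarray, fraction: float, seed: int, scale: float = 5.0
) -> np.ndarray:
    """Replace a fraction of trials with Gaussian noise at ``scale`` x the data s.d.

    The per-cell standard deviation is measured over trials on the input
    data; round(fraction * n_trials) trials (chosen at random) are replaced
    entirely.  Emulates gross artifact contamination for robustness studies.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    data = np.array(data, dtype=float, copy=True)
    n = data.shape[0]
    n_bad = int(round(fraction * n))
    if n_bad == 0:
        return data
    rng = np.random.default_rng(seed)
    bad = rng.choice(n, size=n_bad, replace=False)
    sd = data.std(axis=0)
    data[bad] = rng.normal(0.0, scale * sd, size=(n_bad, *data.shape[1:]))
    return data
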