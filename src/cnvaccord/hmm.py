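"""Five-state Gaussian HMM: Baum-Welch training and Viterbi decoding.

Probe intensities are modelled per SNP as draws from a state-specific
normal distribution, with a homogeneous sticky transition matrix along
the map. Training (EM) runs on a designated reference panel; the fitted
parameters are then frozen and study cohorts are decoded with the
Viterbi maximum-a-posteriori path, independently per individual and per
chromosome. Decoding works in log space; EM uses the classic per-step
scaling, so neither underflows on long chromosomes.

The association layers consume only the integer states, so pipelines
may bypass this module and ingest state matrices directly.
"""

from __future__ import annotations

import numpy as np

from .types import N_STATES, HMMParams, IntensityMatrix, SNPMap, StateMatrix

_LOG2PI = float(np.log(2.0 * np.pi))
_SD_FLOOR = 1e-3
_PROB_FLOOR = 1e-300


def _blocks(n_snps: int, snp_map: SNPMap | None) -> list[tuple[int, int]]:
    if snp_map is None:
        return [(0, n_snps)]
    if len(snp_map) != n_snps:
        raise ValueError("SNP map length does not match the signal dimension")
    return [(a, b) for _, a, b in snp_map.chrom_blocks()]


def _log_emission(x: np.ndarray, params: HMMParams) -> np.ndarray:
    """log N(x | mean_s, sd_s) for every state s; shape (..., 5)."""
    mu = params.means
    sd = params.sds
    z = (x[..., None] - mu) / sd
    return -0.5 * (z * z) - np.log(sd) - 0.5 * _LOG2PI


def viterbi(values: np.ndarray, params: HMMParams) -> tuple[np.ndarray, float]:
    """Most probable state path for one observation sequence.

    Returns ``(path, log_prob)`` where ``log_prob`` is the joint
    log-probability of the returned path and the observations — the
    maximum over all 5**T paths.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    paths, logp = _viterbi_block(values[None, :], params)
    return paths[0], float(logp[0])


def _viterbi_block(x: np.ndarray, params: HMMParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Viterbi over rows of ``x`` (n_individuals, T)."""
    n, T = x.shape
    logB = _log_emission(x, params)  # (n, T, 5)
    with np.errstate(divide="ignore"):
        log_init = np.log(params.initial)
        logA = np.log(params.transition)
    delta = log_init + logB[:, 0]  # (n, 5)
    psi = np.empty((T, n, N_STATES), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None, :, :]  # (n, from, to)
        psi[t] = np.argmax(cand, axis=1)
        delta = np.take_along_axis(cand, psi[t][:, None, :].astype(np.int64), axis=1)[:, 0, :] + logB[:, t]
    paths = np.empty((n, T), dtype=np.int8)
    paths[:, -1] = np.argmax(delta, axis=1)
    logp = np.max(delta, axis=1)
    rows = np.arange(n)
    for t in range(T - 1, 0, -1):
        paths[:, t - 1] = psi[t][rows, paths[:, t].astype(np.int64)]
    return paths, logp


def decode_states(
    signal: IntensityMatrix,
    params: HMMParams,
    snp_map: SNPMap | None = None,
    labels: np.ndarray | None = None,
    cohort_id: str = "decoded",
) -> StateMatrix:
    """Viterbi-decode every individual into integer copy-number states.

    Chromosomes (blocks of ``snp_map``) are decoded independently.
    Decoding itself is label-agnostic; ``labels`` are attached to the
    returned matrix for the association layers (default: all control).
    """
    x = signal.signal
    out = np.empty(x.shape, dtype=np.int8)
    for a, b in _blocks(signal.n_snps, snp_map):
        out[:, a:b], _ = _viterbi_block(x[:, a:b], params)
    if labels is None:
        labels = np.array(["control"] * signal.n_individuals, dtype=object)
    return StateMatrix(states=out, labels=labels, cohort_id=cohort_id)


def log_likelihood(signal: IntensityMatrix, params: HMMParams, snp_map: SNPMap | None = None) -> float:
    """Total observation log-likelihood under the model (scaled forward pass)."""
    total = 0.0
    for a, b in _blocks(signal.n_snps, snp_map):
        B = np.exp(_log_emission(signal.signal[:, a:b], params))
        np.maximum(B, _PROB_FLOOR, out=B)
        alpha = params.initial * B[:, 0]  # (n, 5)
        c = alpha.sum(axis=1)
        alpha /= c[:, None]
        ll = np.log(c)
        for t in range(1, b - a):
            alpha = (alpha @ params.transition) * B[:, t]
            c = alpha.sum(axis=1)
            alpha /= c[:, None]
            ll += np.log(c)
        total += float(ll.sum())
    return total


def baum_welch(
    training: IntensityMatrix,
    init: HMMParams,
    max_iter: int = 50,
    tol: float = 1e-4,
    snp_map: SNPMap | None = None,
) -> tuple[HMMParams, list[float]]:
    """Expectation-maximization fit; returns the parameters and the
    per-iteration log-likelihood history (first entry = under ``init``).

    Stops after ``max_iter`` updates or when the improvement drops below
    ``tol``. ``max_iter=0`` returns ``init`` unchanged. Emission sds are
    floored at 1e-3 to keep the likelihood bounded.
    """
    if training.n_individuals < 1:
        raise ValueError("training data must contain at least one individual")
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    params = init
    history = [log_likelihood(training, params, snp_map)]
    if max_iter == 0:
        return params, history

    blocks = _blocks(training.n_snps, snp_map)
    x = training.signal
    for _ in range(max_iter):
        init_acc = np.zeros(N_STATES)
        xi_acc = np.zeros((N_STATES, N_STATES))
        gw_acc = np.zeros(N_STATES)  # total state occupancy
        gx_acc = np.zeros(N_STATES)  # occupancy-weighted observations
        gx2_acc = np.zeros(N_STATES)

        for a, b in blocks:
            xb = x[:, a:b]
            T = b - a
            B = np.exp(_log_emission(xb, params))
            np.maximum(B, _PROB_FLOOR, out=B)
            n = xb.shape[0]
            alpha = np.empty((T, n, N_STATES))
            c = np.empty((T, n))
            a0 = params.initial * B[:, 0]
            c[0] = a0.sum(axis=1)
            alpha[0] = a0 / c[0][:, None]
            for t in range(1, T):
                at = (alpha[t - 1] @ params.transition) * B[:, t]
                c[t] = at.sum(axis=1)
                alpha[t] = at / c[t][:, None]
            beta = np.empty((T, n, N_STATES))
            beta[-1] = 1.0 / c[-1][:, None]
            for t in range(T - 2, -1, -1):
                beta[t] = (beta[t + 1] * B[:, t + 1]) @ params.transition.T / c[t][:, None]

            gamma = alpha * beta * c[:, :, None]  # (T, n, 5), rows sum to 1
            init_acc += gamma[0].sum(axis=0)
            if T > 1:
                # xi_t(i,j) = alpha_t(i) A(i,j) B_{t+1}(j) beta_{t+1}(j)
                xi_acc += np.einsum(
                    "tni,tnj->ij", alpha[:-1], B[:, 1:].transpose(1, 0, 2) * beta[1:]
                ) * params.transition
            g = gamma.sum(axis=(0, 1))
            gw_acc += g
            gx_acc += np.einsum("tns,nt->s", gamma, xb)
            gx2_acc += np.einsum("tns,nt->s", gamma, xb * xb)

        new_initial = init_acc / init_acc.sum()
        rows = xi_acc.sum(axis=1, keepdims=True)
        new_transition = np.where(rows > 0, xi_acc / np.where(rows > 0, rows, 1.0), params.transition)
        new_transition /= new_transition.sum(axis=1, keepdims=True)
        means = np.where(gw_acc > 0, gx_acc / np.where(gw_acc > 0, gw_acc, 1.0), params.means)
        var = np.where(gw_acc > 0, gx2_acc / np.where(gw_acc > 0, gw_acc, 1.0) - means**2, params.sds**2)
        sds = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        params = HMMParams(new_initial, new_transition, means, sds)

        history.append(log_likelihood(training, params, snp_map))
        if history[-1] - history[-2] < tol:
            break
    return params, history


def fit_hmm(
    training: IntensityMatrix,
    init: HMMParams,
    max_iter: int = 50,
    tol: float = 1e-4,
    snp_map: SNPMap | None = None,
) -> HMMParams:
    """Baum-Welch fit on a reference panel; see :func:`baum_welch`."""
    params, _ = baum_welch(training, init, max_iter=max_iter, tol=tol, snp_map=snp_map)
    return params
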