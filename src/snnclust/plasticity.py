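"""Piecewise STDP rule, spike-pairing bookkeeping and weight clipping.

The learning window is a four-branch piecewise function of the pre/post
interval ``dT = t_post - t_pre`` (strict lower, inclusive upper bounds on
each branch):

* ``20 < dT <= 200`` ms   : fixed depression (non-causal, post much later)
* ``2 < dT <= 20`` ms     : linear potentiation ``slope*dT + intercept``
* ``-200 < dT <= 2`` ms   : small fixed depression (acausal / simultaneous)
* otherwise               : zero

Weights are clipped into ``[g_min, g_max]`` after every update.

Pairing policies
----------------
``"all"`` (default): every (pre spike, post spike) pair within the window
contributes once — direct evaluation of the printed rule per spike pair.
This is the policy under which uncorrelated Poisson firing yields net
depression, the property the self-organization mechanism relies on
(responding neurons are net weakened, rarely-active inputs are pared away).

``"nearest"``: each post spike pairs with the most recent pre spike of the
synapse and each pre spike pairs with the most recent earlier post spike.

The all-pairs policy is implemented with O(n_neurons) rolling band
aggregates per step rather than an explicit pair scan: because the window
has three bands (constant / linear-in-dT / constant), the summed weight
change for a post spike at time t is a linear function of per-band spike
counts and the band-2 age sum, all of which can be maintained incrementally
as spikes age through the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["STDPRule", "PairingBuffer", "stdp_delta", "on_spike_update", "reset_pairing"]


@dataclass(frozen=True)
class STDPRule:
    window_lo: float = -200.0       # ms
    acausal_hi: float = 2.0         # ms
    linear_hi: float = 20.0         # ms
    window_hi: float = 200.0        # ms
    depress_long: float = -0.0125   # uS
    slope: float = -0.0117          # uS/ms
    intercept: float = 0.223        # uS
    depress_acausal: float = -0.0025  # uS
    g_min: float = 0.0              # uS
    g_max: float = 0.25             # uS
    pairing: Literal["all", "nearest"] = "all"

    def __post_init__(self) -> None:
        if not (self.window_lo < self.acausal_hi < self.linear_hi < self.window_hi):
            raise ValueError("window breakpoints must be strictly increasing")
        if self.g_min >= self.g_max:
            raise ValueError("g_min must be below g_max")

    @property
    def zero_crossing(self) -> float:
        """dT at which the linear branch changes sign (~19.06 ms)."""
        return -self.intercept / self.slope


def stdp_delta(dT: np.ndarray | float, rule: STDPRule = STDPRule()) -> np.ndarray | float:
    """Evaluate the learning window at interval(s) ``dT`` (ms).

    Branch bounds are strict below and inclusive above; the result is 0 for
    ``dT <= window_lo`` and ``dT > window_hi``.
    """
    dT_arr = np.asarray(dT, dtype=float)
    if not np.all(np.isfinite(dT_arr)):
        raise ValueError("dT must be finite")
    out = np.zeros_like(dT_arr)
    long_branch = (dT_arr > rule.linear_hi) & (dT_arr <= rule.window_hi)
    lin_branch = (dT_arr > rule.acausal_hi) & (dT_arr <= rule.linear_hi)
    acausal = (dT_arr > rule.window_lo) & (dT_arr <= rule.acausal_hi)
    out[long_branch] = rule.depress_long
    out[lin_branch] = rule.slope * dT_arr[lin_branch] + rule.intercept
    out[acausal] = rule.depress_acausal
    if np.isscalar(dT):
        return float(out)
    return out


def _band_edge(bound: float, dt: float) -> int:
    """Largest spike age (in steps) with ``age*dt <= bound``."""
    return int(np.floor(bound / dt + 1e-9))


class PairingBuffer:
    """Per-population spike-time bookkeeping for one plastic projection.

    Holds the recent spike history of the pre and post populations (within
    the STDP window) and answers, for the current step, (a) the summed
    window value over all in-window pre spikes (for each pre neuron) and
    (b) the number of in-window past post spikes (for each post neuron).
    Cleared at every stimulus-presentation boundary so that no pairing
    spans two input patterns.
    """

    def __init__(self, n_pre: int, n_post: int, rule: STDPRule, dt: float):
        self.rule = rule
        self.dt = float(dt)
        self.n_pre = n_pre
        self.n_post = n_post
        self.t = 0.0
        # Causal side: band edges in steps.  Band 1: ages [0, e1]
        # (dT <= acausal_hi); band 2: (e1, e2]; band 3: (e2, e3].
        self.e1 = _band_edge(rule.acausal_hi, dt)
        self.e2 = _band_edge(rule.linear_hi, dt)
        self.e3 = _band_edge(rule.window_hi, dt)
        # Acausal side: largest post-spike age with age*dt < -window_lo.
        self.a_max = int(np.ceil(-rule.window_lo / dt - 1e-9)) - 1

        if rule.pairing == "all":
            self._ring_pre = np.zeros((self.e3 + 1, n_pre), dtype=np.int16)
            self._ptr_pre = 0
            self._S1 = np.zeros(n_pre)
            self._S2c = np.zeros(n_pre)
            self._S2a = np.zeros(n_pre)
            self._S3 = np.zeros(n_pre)
            self._ring_post = np.zeros((self.a_max + 1, n_post), dtype=np.int16)
            self._ptr_post = 0
            self._post_total = np.zeros(n_post)
            self._post_newest = np.zeros(n_post)
        else:
            self._last_pre = np.full(n_pre, -np.inf)
            self._last_post = np.full(n_post, -np.inf)
            self._acausal_pending = np.zeros(n_post)

    # -- state transitions -------------------------------------------------

    def reset(self) -> None:
        if self.rule.pairing == "all":
            self._ring_pre[:] = 0
            self._S1[:] = 0.0
            self._S2c[:] = 0.0
            self._S2a[:] = 0.0
            self._S3[:] = 0.0
            self._ring_post[:] = 0
            self._post_total[:] = 0.0
            self._post_newest[:] = 0.0
        else:
            self._last_pre[:] = -np.inf
            self._last_post[:] = -np.inf

    def advance(self, pre_spikes: np.ndarray, post_spikes: np.ndarray) -> None:
        """Age the stored histories by one step and record this step's spikes."""
        self.t += self.dt
        pre = pre_spikes.astype(np.int16, copy=False)
        post = post_spikes.astype(np.int16, copy=False)
        if self.rule.pairing == "all":
            ptr, L = self._ptr_pre, self.e3 + 1
            out1 = self._ring_pre[(ptr + self.e1) % L]
            out2 = self._ring_pre[(ptr + self.e2) % L]
            out3 = self._ring_pre[(ptr + self.e3) % L]
            # All band-2 members age one step; the out2 cohort leaves for
            # band 3 and the out1 cohort enters at age e1+1.
            self._S2a += self._S2c
            self._S2a -= (self.e2 + 1) * out2
            self._S2a += (self.e1 + 1) * out1
            self._S2c += out1 - out2
            self._S1 -= out1
            self._S3 += out2 - out3
            self._ptr_pre = (ptr - 1) % L
            self._ring_pre[self._ptr_pre] = pre
            self._S1 += pre

            ptrp, Lp = self._ptr_post, self.a_max + 1
            self._ptr_post = (ptrp - 1) % Lp
            self._post_total -= self._ring_post[self._ptr_post]  # expiring cohort
            self._ring_post[self._ptr_post] = post
            self._post_total += post
            self._post_newest = post.astype(float)
        else:
            self._last_pre[pre_spikes.astype(bool)] = self.t
            # Acausal pairings are applied against posts strictly in the
            # past, so caller queries before we record this step's posts.
            self._pending_post = post_spikes.astype(bool)

    def commit_posts(self) -> None:
        if self.rule.pairing == "nearest":
            self._last_post[self._pending_post] = self.t

    # -- queries -----------------------------------------------------------

    def causal_sum(self) -> np.ndarray:
        """Summed window value over all in-window pre spikes, per pre neuron.

        This is the weight change applied to every connected synapse of a
        post neuron that spikes at the current step (all-pairs policy).
        """
        r = self.rule
        return (
            r.depress_acausal * self._S1
            + r.intercept * self._S2c
            + r.slope * self.dt * self._S2a
            + r.depress_long * self._S3
        )

    def recent_post_count(self) -> np.ndarray:
        """Number of in-window *past* post spikes, per post neuron."""
        return self._post_total - self._post_newest


def on_spike_update(
    pop,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    buffers: PairingBuffer,
    rule: STDPRule | None = None,
) -> None:
    """Apply one step of STDP to a plastic synapse population.

    ``pop`` needs attributes ``W`` (n_pre, n_post) and ``mask`` (bool, same
    shape).  Must be called every step (it also ages the pairing buffers);
    weights are clipped into ``[g_min, g_max]`` in place.
    """
    rule = rule or buffers.rule
    buffers.advance(pre_spikes, post_spikes)
    any_pre = bool(pre_spikes.any())
    any_post = bool(post_spikes.any())

    if rule.pairing == "all":
        if any_post:
            cols = np.flatnonzero(post_spikes)
            delta = buffers.causal_sum()
            block = pop.W[:, cols] + delta[:, None] * pop.mask[:, cols]
            np.clip(block, rule.g_min, rule.g_max, out=block)
            pop.W[:, cols] = block
        if any_pre:
            rows = np.flatnonzero(pre_spikes)
            n_recent = buffers.recent_post_count()
            block = pop.W[rows, :] + rule.depress_acausal * n_recent[None, :] * pop.mask[rows, :]
            np.clip(block, rule.g_min, rule.g_max, out=block)
            pop.W[rows, :] = block
    else:
        t = buffers.t
        if any_post:
            cols = np.flatnonzero(post_spikes)
            seen = np.isfinite(buffers._last_pre)
            dT = np.where(seen, t - buffers._last_pre, 0.0)
            delta = np.where(seen, stdp_delta(dT, rule), 0.0)
            block = pop.W[:, cols] + delta[:, None] * pop.mask[:, cols]
            np.clip(block, rule.g_min, rule.g_max, out=block)
            pop.W[:, cols] = block
        if any_pre:
            rows = np.flatnonzero(pre_spikes)
            dT = buffers._last_post - t          # negative: post strictly earlier
            in_win = np.isfinite(dT) & (dT > rule.window_lo) & (dT < 0)
            delta = np.where(in_win, rule.depress_acausal, 0.0)
            block = pop.W[rows, :] + delta[None, :] * pop.mask[rows, :]
            np.clip(block, rule.g_min, rule.g_max, out=block)
            pop.W[rows, :] = block
        buffers.commit_posts()


def reset_pairing(buffers: PairingBuffer) -> None:
    """Clear all stored spike times (called at each presentation boundary)."""
    buffers.reset()
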