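"""Stochastic ribosome traffic on an mRNA (open-boundary l-TASEP).

Continuous-time Gillespie simulation of ribosomes with a hard-core
footprint (default 10 codons ~ 30 nt) moving along a codon lattice:
initiation at rate alpha when the entry window is free, elongation at rate
k per unblocked ribosome, termination at the stop at rate beta, and an
optional competing readthrough reaction (rate gamma) that carries the
ribosome past the stop. A second ORF downstream (gap in nt, possibly
negative for overlapping start/stop punctuation) allows measuring the
occlusion of downstream initiation by ribosomes idling at the upstream
stop. Only rate ratios matter; time units are arbitrary.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrafficConfig:
    length: int = 150  # codons, first ORF
    footprint: int = 10  # codons (~30 nt)
    alpha: float = 0.1  # initiation, events per unit time (TE proxy)
    k: float = 10.0  # elongation, codons per unit time per unblocked ribosome
    beta: float = 2.0  # termination
    gamma: float = 0.0  # readthrough (competing with termination)
    # optional downstream ORF
    second_orf_length: int = 0  # codons; 0 disables
    gap_nt: int = 30  # signed nt gap between stop and downstream start
    alpha_down: float = 0.1
    beta_down: float = 10.0
    sim_time: float = 1000.0
    burn_in: float = 200.0
    seed: int = 0
    debug_exclusion: bool = False

    def __post_init__(self) -> None:
        if min(self.alpha, self.k, self.beta, self.gamma, self.alpha_down, self.beta_down) < 0:
            raise ValueError("rates must be non-negative")
        if self.footprint < 1:
            raise ValueError("footprint must be at least one codon")
        if self.length <= self.footprint:
            raise ValueError("lattice must be longer than the footprint")
        if self.burn_in >= self.sim_time:
            raise ValueError("burn-in must be shorter than the simulation time")

    @property
    def gap_codons(self) -> int:
        return int(round(self.gap_nt / 3.0))

    def replace(self, **kw) -> "TrafficConfig":
        return TrafficConfig(**{**self.__dict__, **kw})


@dataclass
class TrafficResult:
    occupancy: np.ndarray  # steady-state per-site ribosome (A-site) occupancy
    flux: float  # terminations per unit time, ORF1
    flux_entry: float
    flux_mid: float
    mean_queue: float  # mean contiguous ribosomes stacked at the stop
    flux_down: float = 0.0  # downstream completion flux (if second ORF)
    readthrough_flux: float = 0.0
    time_observed: float = 0.0
    config: TrafficConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.occupancy < -1e-12) or np.any(self.occupancy > 1 + 1e-12):
            raise ValueError("occupancy must lie in [0, 1]")


def simulate_traffic(config: TrafficConfig) -> TrafficResult:
    """Gillespie simulation of the exclusion process; see module docstring.

    Ribosome positions are A-site codon indices, kept sorted; a ribosome at
    position p covers [p, p + footprint) and may advance only if its leader
    is more than a footprint ahead. Initiation places a ribosome at the
    start when the entry window is clear. Occupancy, queue length at the
    stop, and fluxes through the entry, midpoint and stop cross-sections
    are time-averaged after ``burn_in``.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    ell = c.footprint
    L1 = c.length
    stop1 = L1 - 1
    two_orf = c.second_orf_length > 0
    start2 = L1 + c.gap_codons if two_orf else None
    stop2 = start2 + c.second_orf_length - 1 if two_orf else None
    lattice_end = (stop2 + ell if two_orf else stop1 + ell) + 1

    pos: list[int] = []  # sorted A-site positions
    tag: list[int] = []  # 1 = ORF1, 2 = ORF2, 0 = readthrough
    t = 0.0
    occ_accum = np.zeros(lattice_end)
    queue_accum = 0.0
    t_obs = 0.0
    completions1 = completions2 = rt_events = 0
    passed_entry = passed_mid = 0
    mid = L1 // 2

    def window_free(p0: int) -> bool:
        # any ribosome with pos in (p0 - ell, p0 + ell) blocks the window
        i = bisect.bisect_left(pos, p0 - ell + 1)
        return i >= len(pos) or pos[i] >= p0 + ell

    while t < c.sim_time:
        rates: list[float] = []
        actions: list[tuple[str, int]] = []
        if c.alpha > 0 and window_free(0):
            rates.append(c.alpha)
            actions.append(("init1", -1))
        if two_orf and c.alpha_down > 0 and window_free(start2):
            rates.append(c.alpha_down)
            actions.append(("init2", -1))
        n = len(pos)
        for i in range(n):
            p, g = pos[i], tag[i]
            if g == 1 and p == stop1:
                if c.beta > 0:
                    rates.append(c.beta)
                    actions.append(("term", i))
                if c.gamma > 0 and (i == n - 1 or pos[i + 1] - p > ell):
                    rates.append(c.gamma)
                    actions.append(("readthrough", i))
                continue
            if two_orf and g == 2 and p == stop2:
                if c.beta_down > 0:
                    rates.append(c.beta_down)
                    actions.append(("term2", i))
                continue
            if p >= lattice_end - 1:
                rates.append(c.k)
                actions.append(("exit", i))
                continue
            if i == n - 1 or pos[i + 1] - p > ell:
                rates.append(c.k)
                actions.append(("step", i))
        if not rates:
            # absorbing configuration (e.g. beta = 0 with a full lattice):
            # the frozen state persists until the end of the simulation
            if c.sim_time > c.burn_in:
                w = c.sim_time - max(t, c.burn_in)
                if w > 0:
                    for p in pos:
                        if p < lattice_end:
                            occ_accum[p] += w
                    queue_accum += w * _queue_length(pos, stop1, ell)
                    t_obs += w
            break
        total = sum(rates)
        dt = rng.exponential(1.0 / total)
        t_new = min(t + dt, c.sim_time)
        if t_new > c.burn_in:
            w = min(t_new - t, t_new - c.burn_in)
            for p in pos:
                if p < lattice_end:
                    occ_accum[p] += w
            queue_accum += w * _queue_length(pos, stop1, ell)
            t_obs += w
        t = t_new
        if t >= c.sim_time:
            break
        # pick the event
        u = rng.random() * total
        acc = 0.0
        for j, r in enumerate(rates):
            acc += r
            if u <= acc:
                break
        kind, i = actions[j]
        if kind == "init1":
            bisect.insort(pos, 0)
            tag.insert(pos.index(0), 1)
        elif kind == "init2":
            j2 = bisect.bisect_left(pos, start2)
            pos.insert(j2, start2)
            tag.insert(j2, 2)
        elif kind == "term":
            pos.pop(i)
            tag.pop(i)
            if t > c.burn_in:
                completions1 += 1
        elif kind == "term2":
            pos.pop(i)
            tag.pop(i)
            if t > c.burn_in:
                completions2 += 1
        elif kind == "readthrough":
            pos[i] += 1
            tag[i] = 0
            if t > c.burn_in:
                rt_events += 1
        elif kind == "exit":
            pos.pop(i)
            tag.pop(i)
        else:  # step
            old = pos[i]
            pos[i] += 1
            if t > c.burn_in:
                if old == 0:
                    passed_entry += 1
                elif old == mid:
                    passed_mid += 1
        if c.debug_exclusion:
            _assert_exclusion(pos, ell)

    t_obs = max(t_obs, 1e-12)
    return TrafficResult(
        occupancy=occ_accum / t_obs,
        flux=completions1 / t_obs,
        flux_entry=passed_entry / t_obs,
        flux_mid=passed_mid / t_obs,
        mean_queue=queue_accum / t_obs,
        flux_down=completions2 / t_obs,
        readthrough_flux=rt_events / t_obs,
        time_observed=t_obs,
        config=c,
    )


def _queue_length(pos, stop, ell) -> int:
    """Contiguous ribosomes stacked behind (and including) one at the stop."""
    i = bisect.bisect_left(pos, stop)
    if i >= len(pos) or pos[i] != stop:
        return 0
    n = 1
    expect = stop - ell
    j = i - 1
    while j >= 0 and pos[j] == expect:
        n += 1
        expect -= ell
        j -= 1
    return n


def _assert_exclusion(pos, ell) -> None:
    for a, b in zip(pos, pos[1:]):
        assert b - a >= ell, f"exclusion violated: {a}, {b}"


# ------------------------------------------------------------------ sweeps
def queue_vs_te(config: TrafficConfig, alpha_grid) -> list[dict]:
    """Sweep initiation rate (TE proxy) at fixed termination rate.

    Queues lengthen with initiation rate when termination is limiting.
    """
    rows = []
    for j, alpha in enumerate(alpha_grid):
        res = simulate_traffic(config.replace(alpha=float(alpha), seed=config.seed + j))
        rows.append({"alpha": float(alpha), "mean_queue": res.mean_queue, "flux": res.flux})
    return rows


def occlusion_effect(config: TrafficConfig, beta_reduction: float = 60.0) -> dict:
    """Downstream/upstream flux ratio change caused by slow termination.

    FC = (flux_down / flux_up) at beta / beta_reduction divided by the same
    ratio at the reference beta. FC <= 1 when the terminating ribosome's
    footprint overlaps the downstream initiation region; FC ~ 1 for gaps
    much larger than a footprint or when beta is unperturbed
    (beta_reduction = 1).
    """
    if config.second_orf_length <= 0:
        raise ValueError("occlusion_effect needs a second ORF")
    ref = simulate_traffic(config)
    slow = simulate_traffic(
        config.replace(beta=config.beta / beta_reduction, seed=config.seed + 1)
    )
    ratio_ref = ref.flux_down / ref.flux if ref.flux > 0 else math.nan
    ratio_slow = slow.flux_down / slow.flux if slow.flux > 0 else math.nan
    fc = ratio_slow / ratio_ref if ratio_ref and not math.isnan(ratio_ref) else math.nan
    return {
        "fc": fc,
        "ratio_reference": ratio_ref,
        "ratio_slow": ratio_slow,
        "reference": ref,
        "slow": slow,
    }
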