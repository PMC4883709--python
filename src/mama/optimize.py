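"""Sequential hyperparameter optimization driven by repeated simulation.

The three knobs -- similarity power nu, ratio power tau, and the number of
motif-pair features n_mp -- are tuned one after another:

* nu: starting at 1, each nu is scored by the mean AUC (AoAR) over
  tau in {1..5} x repeats; nu grows while AoAR does not decrease, and the
  first decrease returns nu - 1.
* tau: at each tau, the five values {tau .. tau+4} x repeats are run and
  the least-squares slope of AUC against tau (SoAR) is computed; the
  running maximum slope is tracked, and the loop stops when the current
  slope falls below half that maximum.
* n_mp: each tested value is scored by mean AUC over repeats; the argmax
  wins (ties to the smaller value).

All operations talk to the pipeline through a single callable
``runner(nu, tau, n_mp, seed) -> auc``, so constructed response surfaces
can exercise the decision rules directly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatPolicy",
    "OptState",
    "optimize_nu",
    "optimize_tau",
    "optimize_nmp",
    "parameter_effect_analysis",
    "NMP_TEST_VALUES",
]

Runner = Callable[[int, float, int, int], float]

NMP_TEST_VALUES = [1, 2, 3, 5, 10, 20, 30, 50, 100, 200]
NU_CAP = 8
TAU_CAP = 30


@dataclass(frozen=True)
class RepeatPolicy:
    repeats_per_cell: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats_per_cell < 1:
            raise ValueError("repeats_per_cell must be >= 1")


@dataclass
class OptState:
    """Trajectory record of one optimization run."""

    nu: int = 1
    tau: float = 1.0
    n_mp: int = 0
    history: list[tuple[int, float, int, int, float]] = field(default_factory=list)
    aoar_records: dict = field(default_factory=dict)
    soar_records: dict = field(default_factory=dict)
    max_soar: float = float("nan")

    def record(self, nu: int, tau: float, n_mp: int, seed: int, auc: float) -> None:
        self.history.append((nu, tau, n_mp, seed, auc))


class _SeedStream:
    """Deterministic distinct seeds for every simulation cell."""

    def __init__(self, base_seed: int) -> None:
        self._counter = itertools.count()
        self._base = base_seed

    def next(self) -> int:
        return self._base * 1_000_003 + next(self._counter)


def _cell_aucs(
    runner: Runner,
    nu: int,
    taus: Sequence[float],
    n_mp: int,
    policy: RepeatPolicy,
    seeds: _SeedStream,
    state: OptState,
) -> list[tuple[float, float]]:
    """(tau, auc) for every tau x repeat in one optimization cell."""
    out: list[tuple[float, float]] = []
    for tau in taus:
        for _ in range(policy.repeats_per_cell):
            seed = seeds.next()
            try:
                auc = runner(nu, tau, n_mp, seed)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed at nu={nu}, tau={tau}, n_mp={n_mp}, seed={seed}"
                ) from exc
            state.record(nu, tau, n_mp, seed, auc)
            out.append((tau, auc))
    return out


def optimize_nu(
    runner: Runner,
    policy: RepeatPolicy = RepeatPolicy(),
    n_mp: int = 0,
    nu_cap: int = NU_CAP,
    state: OptState | None = None,
) -> int:
    """Increase nu while the mean AUC over tau in {1..5} keeps rising."""
    state = state if state is not None else OptState()
    seeds = _SeedStream(policy.base_seed)
    taus = [1.0, 2.0, 3.0, 4.0, 5.0]
    prev_aoar = -np.inf
    nu = 1
    while True:
        runs = _cell_aucs(runner, nu, taus, n_mp, policy, seeds, state)
        aoar = float(np.mean([a for _, a in runs]))
        state.aoar_records[("nu", nu)] = aoar
        logger.info("AoAR(nu=%d) = %.4f", nu, aoar)
        # non-improvement (incl. exact ties) stops the climb; only the
        # measure-zero tie case differs from a strict decrease test
        if aoar <= prev_aoar:
            state.nu = nu - 1
            return nu - 1
        if nu >= nu_cap:
            logger.warning("nu reached its cap %d without a decrease", nu_cap)
            state.nu = nu
            return nu
        prev_aoar = aoar
        nu += 1


def _tau_step(tau: float) -> float:
    # read of "add 5/tau once tau exceeds five": never advance by < 1
    return 1.0 if tau <= 5 else max(1.0, round(5.0 / tau))


def optimize_tau(
    runner: Runner,
    nu: int,
    policy: RepeatPolicy = RepeatPolicy(),
    n_mp: int = 0,
    tau_cap: float = TAU_CAP,
    state: OptState | None = None,
) -> float:
    """Advance tau until the AUC-vs-tau slope halves from its maximum."""
    state = state if state is not None else OptState(nu=nu)
    seeds = _SeedStream(policy.base_seed + 1)
    tau = 1.0
    max_soar = float("nan")
    while True:
        taus = [tau + k for k in range(5)]
        runs = _cell_aucs(runner, nu, taus, n_mp, policy, seeds, state)
        x = np.array([t for t, _ in runs])
        y = np.array([a for _, a in runs])
        soar = float(np.polyfit(x, y, 1)[0])
        state.soar_records[tau] = soar
        if np.isnan(max_soar) or soar > max_soar:
            max_soar = soar
        state.max_soar = max_soar
        logger.info("SoAR(tau=%.3g) = %.5f (max %.5f)", tau, soar, max_soar)
        if soar < max_soar / 2:
            state.tau = tau
            return tau
        if tau >= tau_cap:
            logger.warning("tau reached its cap %.3g without plateauing", tau_cap)
            state.tau = tau
            return tau
        tau += _tau_step(tau)


def optimize_nmp(
    runner: Runner,
    nu: int,
    tau: float,
    policy: RepeatPolicy = RepeatPolicy(),
    test_values: Sequence[int] = NMP_TEST_VALUES,
    state: OptState | None = None,
) -> int:
    """Pick the tested n_mp with the highest mean AUC (ties -> smaller)."""
    state = state if state is not None else OptState(nu=nu, tau=tau)
    seeds = _SeedStream(policy.base_seed + 2)
    if not test_values:
        logger.warning("no n_mp values to test; returning 0")
        state.n_mp = 0
        return 0
    best_value, best_aoar = None, -np.inf
    for n_mp in sorted(test_values):
        runs = _cell_aucs(runner, nu, [tau], n_mp, policy, seeds, state)
        aoar = float(np.mean([a for _, a in runs]))
        state.aoar_records[("n_mp", n_mp)] = aoar
        logger.info("AoAR(n_mp=%d) = %.4f", n_mp, aoar)
        if aoar > best_aoar:
            best_value, best_aoar = n_mp, aoar
    assert best_value is not None
    state.n_mp = best_value
    return best_value


def parameter_effect_analysis(
    grid_results: Mapping[tuple[int, float, int], Sequence[float]],
) -> dict[str, float]:
    """Effect of each knob: range of its marginal mean AUC over the grid.

    ``grid_results`` maps (nu, tau, n_mp) -> AUCs and must be a complete
    factorial grid.
    """
    keys = list(grid_results)
    if not keys:
        raise ValueError("empty grid")
    nus = sorted({k[0] for k in keys})
    taus = sorted({k[1] for k in keys})
    nmps = sorted({k[2] for k in keys})
    expected = {(a, b, c) for a in nus for b in taus for c in nmps}
    missing = expected - set(keys)
    if missing:
        raise ValueError(f"incomplete factorial grid; missing cells: {sorted(missing)}")
    if len(keys) < 2:
        raise ValueError("grid must contain more than one cell")

    def marginal(axis: int, values: list) -> dict:
        return {
            v: float(
                np.mean(
                    [np.mean(grid_results[k]) for k in keys if k[axis] == v]
                )
            )
            for v in values
        }

    effects = {}
    for name, axis, values in (("nu", 0, nus), ("tau", 1, taus), ("n_mp", 2, nmps)):
        marg = marginal(axis, values)
        effects[name] = max(marg.values()) - min(marg.values())
    return effects
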