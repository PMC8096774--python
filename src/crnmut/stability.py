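"""Monte-Carlo verification of per-class global stability.

If every stoichiometric compatibility class holds a unique globally
asymptotically stable steady state, then many trajectories started from
scattered points of one class must all land on that state.  The protocol:
draw a handful of random classes (log10-uniform total concentrations),
scatter a fixed number of initial points in each, integrate all of them
over the same long window, and compare the per-species coefficient of
variation of the initial values (eps_0) with that of the terminal values
(eps_e).  Convergence to a single state shows up as eps_e collapsing at
least an order of magnitude below eps_0 in every class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import CLASS_RANGE, random_class, same_class, sample_class_point
from .conservation import ConservationSet
from .dynamics import T_END_DEFAULT, integrate_to_steady
from .errors import ContractError
from .network import ReactionNetwork

__all__ = ["StabilityReport", "ClassRecord", "coefficient_of_variation",
           "verify_global_stability"]


def coefficient_of_variation(samples) -> float:
    """Sample standard deviation (denominator m - 1) over the mean.

    Undefined (NaN) when the mean is not positive; m < 2 is a contract
    error.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 2:
        raise ContractError("coefficient of variation needs >= 2 samples")
    mu = samples.mean()
    if mu <= 0:
        return float("nan")
    return float(samples.std(ddof=1) / mu)


@dataclass
class ClassRecord:
    c: np.ndarray
    n_points: int
    eps0: np.ndarray            # per reported species
    eps_e: np.ndarray
    mu_e: np.ndarray
    species: list[str]          # names of reported (non-constant) species
    excluded_zero_mean: list[str] = field(default_factory=list)
    failed_points: list[int] = field(default_factory=list)
    complete: bool = True

    def mean_eps0(self) -> float:
        return float(np.nanmean(self.eps0))

    def mean_eps_e(self) -> float:
        return float(np.nanmean(self.eps_e))


@dataclass
class StabilityReport:
    classes: list[ClassRecord]
    separation: float
    passed: bool
    summary: dict = field(default_factory=dict)
    worst_species: list[tuple[str, float]] = field(default_factory=list)


def verify_global_stability(net: ReactionNetwork, cs: ConservationSet,
                            n_classes: int = 5, n_points: int = 30,
                            c_range: tuple[float, float] = CLASS_RANGE,
                            t_end: float = T_END_DEFAULT,
                            seed: int | None = None,
                            separation: float = 10.0,
                            rtol: float = 1e-6, atol: float = 1e-12,
                            ) -> StabilityReport:
    """Run the sampling-and-integration protocol and build the report.

    ``passed`` is True when, in every class, the mean (over non-constant
    species) terminal coefficient of variation is at least ``separation``
    times below the mean initial one.  One master seed drives a dedicated
    substream per class, so the report is bit-for-bit reproducible.
    """
    cs.require_elemental("verify_global_stability")
    if n_points < 2:
        raise ContractError("n_points must be >= 2 (CV undefined otherwise)")
    master = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(n_classes)]

    non_const = [i for i, s in enumerate(net.species) if not s.is_constant]
    names = [net.species[i].name for i in non_const]
    records: list[ClassRecord] = []
    for rng in streams:
        c = random_class(cs, rng, c_range)
        points = [sample_class_point(cs, c, rng) for _ in range(n_points)]
        for pt in points:
            if not same_class(cs, points[0], pt):
                raise ContractError(
                    "sampled point left its compatibility class")
        X0 = np.stack(points, axis=1)
        Xe = np.full_like(X0, np.nan)
        failed = []
        for kidx in range(n_points):
            try:
                res = integrate_to_steady(net, X0[:, kidx], t_end=t_end,
                                          rtol=rtol, atol=atol,
                                          conservation=cs)
                Xe[:, kidx] = res.x_e
            except Exception:
                failed.append(kidx)
        ok = [kidx for kidx in range(n_points) if kidx not in failed]
        eps0 = np.full(len(non_const), np.nan)
        eps_e = np.full(len(non_const), np.nan)
        mu_e = np.full(len(non_const), np.nan)
        excluded = []
        for a, i in enumerate(non_const):
            eps0[a] = _cv_or_nan(X0[i, ok])
            mu_e[a] = np.mean(Xe[i, ok]) if ok else np.nan
            if mu_e[a] and mu_e[a] > 0:
                eps_e[a] = _cv_or_nan(Xe[i, ok])
            else:
                excluded.append(names[a])
        records.append(ClassRecord(
            c=c, n_points=n_points, eps0=eps0, eps_e=eps_e, mu_e=mu_e,
            species=names, excluded_zero_mean=excluded,
            failed_points=failed, complete=not failed))

    passed = all(
        rec.complete
        and np.isfinite(rec.mean_eps_e())
        and rec.mean_eps_e() * separation <= rec.mean_eps0()
        for rec in records)

    all_eps0 = np.concatenate([r.eps0 for r in records])
    all_eps_e = np.concatenate([r.eps_e for r in records])
    summary = {
        "mean_eps0": float(np.nanmean(all_eps0)),
        "sem_eps0": _sem(all_eps0),
        "mean_eps_e": float(np.nanmean(all_eps_e)),
        "sem_eps_e": _sem(all_eps_e),
        "n_classes": n_classes,
        "n_points": n_points,
    }
    pooled: dict[str, float] = {}
    for rec in records:
        for name, v in zip(rec.species, rec.eps_e):
            if np.isfinite(v):
                pooled[name] = max(pooled.get(name, 0.0), float(v))
    worst = sorted(pooled.items(), key=lambda kv: -kv[1])[:10]
    return StabilityReport(classes=records, separation=separation,
                           passed=passed, summary=summary,
                           worst_species=worst)


def _cv_or_nan(samples: np.ndarray) -> float:
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2 or samples.mean() <= 0:
        return float("nan")
    return float(samples.std(ddof=1) / samples.mean())


def _sem(values: np.ndarray) -> float:
    v = values[np.isfinite(values)]
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))
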