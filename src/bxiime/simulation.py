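"""Bias/MSE simulation harness and the synthetic fixture generator.

The simulation mirrors the classical estimator-comparison design: draw N
replicate samples at each size n from a BXII-ME with known truth, fit every
requested estimator, and report the empirical mean, bias and MSE per
(method, size, parameter):

    bias = (1/N) sum (h_hat_i - h),    mse = (1/N) sum (h_hat_i - h)^2.

A single master seed spawns independent substreams per (size, replicate),
so any cell can be reproduced in isolation; within a replicate all methods
see the same data.  Replicates whose optimiser did not converge are dropped
from the averages and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distribution import Params, Sample, as_params, sample as draw_sample
from .estimation import METHODS, EstimationConfig, fit
from .exceptions import DomainError

__all__ = ["SimDesign", "SimResult", "run_simulation", "generate_fixture"]

_PARAM_NAMES = ("alpha", "beta", "lam")


@dataclass(frozen=True)
class SimDesign:
    """Design of a bias/MSE experiment."""

    truth: Params
    sizes: tuple[int, ...] = (20, 50, 100, 200, 400)
    replications: int = 250
    methods: tuple[str, ...] = METHODS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "truth", as_params(self.truth))
        sizes = tuple(int(s) for s in self.sizes)
        if not sizes or any(b <= a for a, b in zip(sizes, sizes[1:])) or sizes[0] < 4:
            raise DomainError("sizes must be an increasing sequence of counts >= 4")
        object.__setattr__(self, "sizes", sizes)
        if self.replications < 1:
            raise DomainError("replications must be >= 1")
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise DomainError(f"unknown methods: {sorted(bad)}")
        object.__setattr__(self, "methods", tuple(self.methods))


@dataclass(frozen=True)
class SimResult:
    """Tidy results table with one row per (method, n, parameter)."""

    design: SimDesign
    table: pd.DataFrame  # columns: method, n, parameter, mean, bias, mse, n_used, n_failed

    def cell(self, method: str, n: int, parameter: str) -> pd.Series:
        t = self.table
        row = t[(t.method == method) & (t.n == n) & (t.parameter == parameter)]
        if row.empty:
            raise KeyError((method, n, parameter))
        return row.iloc[0]


def run_simulation(design: SimDesign) -> SimResult:
    """Run the full bias/MSE experiment described by `design`."""
    truth = np.asarray(design.truth.as_tuple())
    master = np.random.SeedSequence(design.seed)
    size_seeds = master.spawn(len(design.sizes))
    rows = []
    for n, size_seed in zip(design.sizes, size_seeds):
        rep_seeds = size_seed.spawn(design.replications)
        est = {m: [] for m in design.methods}
        failed = {m: 0 for m in design.methods}
        for rs in rep_seeds:
            rng = np.random.default_rng(rs)
            data = draw_sample(n, design.truth, seed=rng)
            cfg = EstimationConfig(multistart=1)
            for m in design.methods:
                res = fit(data, m, cfg)
                if res.converged:
                    est[m].append(res.estimates.as_tuple())
                else:
                    failed[m] += 1
        for m in design.methods:
            if not est[m]:
                rows.extend(
                    dict(method=m, n=n, parameter=pn, mean=np.nan, bias=np.nan,
                         mse=np.nan, n_used=0, n_failed=failed[m])
                    for pn in _PARAM_NAMES
                )
                continue
            E = np.asarray(est[m])
            for j, pn in enumerate(_PARAM_NAMES):
                dev = E[:, j] - truth[j]
                rows.append(
                    dict(
                        method=m, n=n, parameter=pn,
                        mean=float(E[:, j].mean()),
                        bias=float(dev.mean()),
                        mse=float((dev**2).mean()),
                        n_used=E.shape[0],
                        n_failed=failed[m],
                    )
                )
    return SimResult(design=design, table=pd.DataFrame(rows))


def generate_fixture(n: int, params, seed: int, path) -> Path:
    """Write n BXII-ME draws to `path`, one value per line, plus a JSON
    sidecar `<path>.meta.json` recording the parameters and seed.

    Stands in for external application datasets: a reproducible, exactly
    specified positive-lifetime sample.
    """
    p = as_params(params)
    out = Path(path)
    s = draw_sample(int(n), p, seed=seed)
    try:
        out.write_text("".join(f"{float(v)!r}\n" for v in s.values))
        sidecar = out.with_name(out.name + ".meta.json")
        sidecar.write_text(
            json.dumps(
                {"n": int(n), "alpha": p.alpha, "beta": p.beta, "lam": p.lam,
                 "seed": int(seed), "method": "inverse"},
                indent=2,
            )
            + "\n"
        )
    except OSError as exc:
        raise OSError(f"cannot write fixture to {out}: {exc}") from exc
    return out
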