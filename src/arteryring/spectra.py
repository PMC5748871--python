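"""Parameter sweeps producing peak-response tables ("response spectra").

A response spectrum tabulates, against one or two problem parameters, the
peak value of each response quantity over the cardiac cycle — the ring
analogue of an earthquake-engineering shock spectrum. Every grid point is
simulated independently from identical initial conditions, so rows are
order-independent.

``builtin_fixture`` encodes the figure/table parameter sets of the study
conditions (pre-stretch ranges, stiffness ratios, normalized pressures and
time ratios); grid resolutions inside stated ranges default to 7-11 evenly
spaced points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DimensionlessGroups
from .solver import SolverSettings, simulate, summarize

__all__ = ["SweepSpec", "sweep", "builtin_fixture", "FIXTURES"]

_ALL_QUANTITIES = ("ur_over_R", "lam_theta", "h_over_H", "W_norm",
                   "stress_theta_norm", "stress_z_norm")


@dataclass(frozen=True)
class SweepSpec:
    """One- or two-parameter sweep over dimensionless ring problems.

    ``varying`` maps group-field names (``lam_z0``, ``material_ratio``,
    ``p_hat_s``, ``time_ratio``, ``order``) to strictly monotone grids.
    """

    base: DimensionlessGroups
    varying: tuple = ()
    quantities: tuple = _ALL_QUANTITIES

    def __post_init__(self):
        if not 1 <= len(self.varying) <= 2:
            raise ValueError("one or two varying parameters required")
        for name, grid in self.varying:
            grid = np.asarray(grid, dtype=float)
            if grid.size == 0:
                raise ValueError(f"empty grid for {name!r}")
            if grid.size > 1 and not (np.all(np.diff(grid) > 0)
                                      or np.all(np.diff(grid) < 0)):
                raise ValueError(f"grid for {name!r} must be strictly monotone")


def sweep(spec: SweepSpec, settings: SolverSettings | None = None) -> pd.DataFrame:
    """Run the sweep; one row per grid point.

    Failures at individual points are recorded in the ``error`` column and
    the sweep continues.
    """
    settings = settings or SolverSettings()
    names = [n for n, _ in spec.varying]
    grids = [np.asarray(g, dtype=float) for _, g in spec.varying]
    rows = []
    for combo in itertools.product(*grids):
        kw = dict(zip(names, combo))
        if "order" in kw:
            kw["order"] = int(kw["order"])
        row = dict(kw)
        try:
            trace = simulate(spec.base.with_(**kw), settings)
            summ = summarize(trace)
            for q in spec.quantities:
                pk = summ[q]
                row[f"{q}_peak"] = pk.value
                row[f"{q}_t_peak_s"] = pk.t_peak_s
            row["diverged"] = summ.diverged
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def _lz_grid():
    return np.arange(1.0, 1.3001, 0.05)


def _lin(a, b, n):
    return np.linspace(a, b, n)


_T_H = 1.0 / 3e-4  # figure-default cardiac-period to characteristic-time ratio


def _fixtures():
    sk = lambda **kw: DimensionlessGroups(law="skalak", **kw)  # noqa: E731
    ha = lambda **kw: DimensionlessGroups(law="hariton", **kw)  # noqa: E731
    mr = lambda **kw: DimensionlessGroups(law="mooney_rivlin", **kw)  # noqa: E731
    return {
        "table1": SweepSpec(sk(p_hat_s=0.16, time_ratio=2000.0),
                            (("lam_z0", _lz_grid()),
                             ("material_ratio", [0.0, 0.5, 1.0]))),
        "table2": SweepSpec(ha(p_hat_s=3.2, time_ratio=_T_H),
                            (("lam_z0", _lz_grid()),
                             ("material_ratio", [5.0, 15.0, 25.0]))),
        "table3": SweepSpec(ha(material_ratio=15.0, time_ratio=_T_H),
                            (("lam_z0", _lz_grid()),
                             ("p_hat_s", [0.8, 2.4, 4.0]))),
        "table4": SweepSpec(mr(p_hat_s=0.32, time_ratio=1000.0),
                            (("lam_z0", _lz_grid()),
                             ("material_ratio", [-0.5, 0.0, 0.5]))),
        "table5": SweepSpec(mr(material_ratio=0.0, time_ratio=1000.0),
                            (("lam_z0", _lz_grid()),
                             ("p_hat_s", [0.16, 0.32, 0.48]))),
        "fig4a": SweepSpec(sk(material_ratio=0.0, p_hat_s=0.16,
                              time_ratio=2000.0),
                           (("lam_z0", _lz_grid()),)),
        "fig4b": SweepSpec(sk(lam_z0=1.0, p_hat_s=0.16, time_ratio=2000.0),
                           (("material_ratio", _lin(0, 1, 11)),)),
        "fig5a": SweepSpec(sk(material_ratio=0.0, lam_z0=1.0,
                              time_ratio=2000.0),
                           (("p_hat_s", _lin(0.16, 1.28, 8)),)),
        "fig5b": SweepSpec(sk(material_ratio=0.0, lam_z0=1.0, p_hat_s=0.16),
                           (("time_ratio", _lin(1000, 10000, 10)),)),
        "fig6": SweepSpec(sk(lam_z0=1.0, time_ratio=2000.0),
                          (("material_ratio", _lin(0, 1, 11)),
                           ("p_hat_s", [0.16, 0.32, 0.48]))),
        "fig7a": SweepSpec(ha(material_ratio=16.7, p_hat_s=3.2,
                              time_ratio=_T_H),
                           (("lam_z0", _lz_grid()),)),
        "fig7b": SweepSpec(ha(lam_z0=1.25, p_hat_s=3.2, time_ratio=_T_H),
                           (("material_ratio", _lin(2, 26, 7)),)),
        "fig8a": SweepSpec(ha(lam_z0=1.25, material_ratio=16.7,
                              time_ratio=_T_H),
                           (("p_hat_s", _lin(0.5, 2.3, 7)),)),
        "fig8b": SweepSpec(ha(lam_z0=1.25, material_ratio=16.7, p_hat_s=3.2),
                           (("time_ratio", _lin(500, 5000, 7)),)),
        "fig9": SweepSpec(ha(lam_z0=1.0, time_ratio=_T_H),
                          (("material_ratio", _lin(5, 25, 5)),
                           ("p_hat_s", [0.8, 2.4, 4.0]))),
        "fig10a": SweepSpec(mr(material_ratio=0.0, p_hat_s=0.64,
                               time_ratio=1000.0),
                            (("lam_z0", _lz_grid()),)),
        "fig10b": SweepSpec(mr(lam_z0=1.1, p_hat_s=0.64, time_ratio=1000.0),
                            (("material_ratio", _lin(-0.5, 0.5, 11)),)),
        "fig11a": SweepSpec(mr(lam_z0=1.0, material_ratio=0.0,
                               time_ratio=1000.0),
                            (("p_hat_s", _lin(0.08, 0.8, 10)),)),
        "fig11b": SweepSpec(mr(lam_z0=1.0, material_ratio=0.0, p_hat_s=0.64),
                            (("time_ratio", _lin(1000, 5000, 5)),)),
        "fig12": SweepSpec(mr(lam_z0=1.1, time_ratio=1000.0),
                           (("material_ratio", _lin(-0.5, 0.5, 11)),
                            ("p_hat_s", [0.16, 0.32, 0.48]))),
    }


FIXTURES = tuple(sorted(_fixtures()))


def builtin_fixture(name: str) -> SweepSpec:
    """Return the fully populated sweep for a named figure/table fixture."""
    try:
        return _fixtures()[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        ) from None
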