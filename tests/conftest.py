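"""Shared fixtures: one default synthetic pipeline run and a brute-force
CHONS mass-grid oracle for formula-assignment tests."""

from __future__ import annotations

import numpy as np
import pytest

from flumeflux import ftms
from flumeflux.pipeline import RunConfig, run


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The full synthetic analysis at the default seeded configuration.

    Shared across test modules: generating the six-flume experiment and
    running every stage once is enough for all end-to-end assertions.
    """
    out = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(seed=0, outdir=str(out))
    return run(cfg)


class MassGridOracle:
    """Unpruned enumeration of every CHONS composition up to a mass cap.

    Independent of the assignment search path: builds the complete
    (c, h, o, n, s) grid with no validity filtering, sorts by exact mass,
    and answers window queries by bisection.
    """

    def __init__(self, max_mass: float = 820.0):
        mc, mh, mo, mn, ms = (ftms.MASS[e] for e in "CHONS")
        c = np.arange(1, min(100, int(max_mass // mc)) + 1, dtype=np.int16)
        # h cap: 2c + 2 + n (valence limit) for the largest c in range
        h = np.arange(0, 2 * int(c[-1]) + 8, dtype=np.int16)
        o = np.arange(0, min(80, int(max_mass // mo)) + 1, dtype=np.int16)
        n = np.arange(0, 6, dtype=np.int16)
        s = np.arange(0, 2, dtype=np.int16)
        C, H, O, N, S = np.meshgrid(c, h, o, n, s, indexing="ij", sparse=False)
        comp = np.column_stack([a.ravel() for a in (C, H, O, N, S)])
        mass = (comp[:, 0] * mc + comp[:, 1] * mh + comp[:, 2] * mo
                + comp[:, 3] * mn + comp[:, 4] * ms)
        keep = mass <= max_mass
        comp, mass = comp[keep], mass[keep]
        order = np.argsort(mass)
        self.comp = comp[order]
        self.mass = mass[order]

    def query(self, neutral_mass: float, tol_ppm: float) -> tuple[np.ndarray, np.ndarray]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.mass, neutral_mass - tol, side="left")
        hi = np.searchsorted(self.mass, neutral_mass + tol, side="right")
        return self.comp[lo:hi], self.mass[lo:hi]


@pytest.fixture(scope="session")
def mass_grid_oracle():
    return MassGridOracle()
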