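"""Ultrahigh-resolution mass spectrometry of the dissolved organic carbon pool.

Negative-mode FTICR-MS peak lists (m/z, intensity) from the flume inflow and
from each flume's residual (post-recirculation) sample are processed to

* assign CHONS elemental formulas to [M-H]- ions by exhaustive search under
  elemental caps (C<=100, O<=80, N<=5, S<=1) and standard validity filters,
* compute formula descriptors: double bond equivalents (DBE), O:C and H:C
  ratios and a modified aromaticity index (AI),
* restrict analysis to the compounds detected in the inflow AND every
  residual sample (guards against in-flume production and sensitivity
  artifacts),
* derive compound-specific mass transfer coefficients from intensity ratios,
  and Shannon diversity/evenness of the DOC pool from relative intensities.

Compound-specific mass transfer assumes each compound decays first-order
during recirculation of duration T over a water column of depth equivalent
h_bar, giving ``v_f = (h_bar/T) * ln(I_inflow / I_residual)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MASS",
    "PROTON_MASS",
    "Formula",
    "CompoundTable",
    "AssignmentConstraints",
    "assign_formula",
    "descriptors",
    "shared_compound_set",
    "compound_vf",
    "doc_pool_diversity",
    "van_krevelen",
]

# Monoisotopic atomic masses, Da (CODATA / IUPAC 2021)
MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "S": 31.97207100,
}
PROTON_MASS = 1.007276466812


@dataclass(frozen=True)
class AssignmentConstraints:
    """Elemental caps and validity filters for formula assignment."""

    max_c: int = 100
    max_o: int = 80
    max_n: int = 5
    max_s: int = 1
    hc_min: float = 0.3
    hc_max: float = 2.5
    oc_max: float = 1.2


@dataclass(frozen=True)
class Formula:
    """A neutral CHONS elemental composition with derived descriptors."""

    c: int
    h: int
    o: int
    n: int
    s: int
    neutral_mass: float
    error_ppm: float
    dbe: float
    oc: float
    hc: float
    ai: float
    has_n: bool
    ambiguous: bool = field(default=False)

    def __str__(self) -> str:
        parts = [f"C{self.c}", f"H{self.h}"]
        for sym, cnt in (("O", self.o), ("N", self.n), ("S", self.s)):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)


def exact_mass(c: int, h: int, o: int, n: int, s: int) -> float:
    """Monoisotopic neutral mass of a CHONS composition."""
    return c * MASS["C"] + h * MASS["H"] + o * MASS["O"] + n * MASS["N"] + s * MASS["S"]


def descriptors(c: int, h: int, o: int, n: int, s: int) -> tuple[float, float, float, float]:
    """(DBE, O:C, H:C, AI) for a CHONS composition.

    DBE = 1 + C - H/2 + N/2 (rings plus double bonds of the neutral
    even-electron molecule).  AI is the modified aromaticity index with half
    of oxygen assumed in carbonyl-like bonds:
    ``(1 + C - O/2 - S - H/2) / (C - O/2 - N - S)``, clamped to 0 when the
    denominator is non-positive or the value negative.
    """
    if c <= 0:
        raise ValueError("need at least one carbon")
    dbe = 1.0 + c - h / 2.0 + n / 2.0
    oc = o / c
    hc = h / c
    denom = c - 0.5 * o - n - s
    if denom <= 0:
        ai = 0.0
    else:
        ai = (1.0 + c - 0.5 * o - s - 0.5 * h) / denom
        if ai < 0:
            ai = 0.0
    return dbe, oc, hc, ai


def _candidates(neutral_mass: float, tol_ppm: float,
                con: AssignmentConstraints) -> pd.DataFrame:
    """All valid CHONS compositions within tol of a neutral mass (vectorized)."""
    tol_da = neutral_mass * tol_ppm * 1e-6
    rows = []
    c_hi = min(con.max_c, int(neutral_mass // MASS["C"]))
    c_grid = np.arange(1, c_hi + 1)
    for n in range(con.max_n + 1):
        for s in range(con.max_s + 1):
            rem_ns = neutral_mass - n * MASS["N"] - s * MASS["S"]
            if rem_ns <= 0:
                continue
            o_hi = min(con.max_o, int(rem_ns // MASS["O"]))
            o_grid = np.arange(0, o_hi + 1)
            # remainder after C and O for the full (c, o) grid
            rem = rem_ns - c_grid[:, None] * MASS["C"] - o_grid[None, :] * MASS["O"]
            h_near = np.round(rem / MASS["H"]).astype(int)
            for dh in (0, -1, 1):  # neighbours catch rounding at the tol edge
                h = h_near + dh
                mass = (neutral_mass - rem) + h * MASS["H"] + n * MASS["N"] + s * MASS["S"]
                # rebuild exactly to avoid accumulation error
                mass = (c_grid[:, None] * MASS["C"] + o_grid[None, :] * MASS["O"]
                        + h * MASS["H"] + n * MASS["N"] + s * MASS["S"])
                err = mass - neutral_mass
                ok = (np.abs(err) <= tol_da) & (h >= 0)
                ok &= (h + n) % 2 == 0  # integer DBE for an even-electron neutral
                ci, oi = np.nonzero(ok)
                for k in range(ci.size):
                    c = int(c_grid[ci[k]])
                    o = int(o_grid[oi[k]])
                    hh = int(h[ci[k], oi[k]])
                    dbe, oc, hc, ai = descriptors(c, hh, o, n, s)
                    if dbe < 0 or not (con.hc_min <= hc <= con.hc_max) or oc > con.oc_max:
                        continue
                    rows.append((c, hh, o, n, s, float(mass[ci[k], oi[k]]),
                                 float(err[ci[k], oi[k]] / neutral_mass * 1e6),
                                 dbe, oc, hc, ai))
    cols = ["c", "h", "o", "n", "s", "mass", "error_ppm", "dbe", "oc", "hc", "ai"]
    df = pd.DataFrame(rows, columns=cols)
    return df.drop_duplicates(subset=["c", "h", "o", "n", "s"])


def assign_formula(mz: float, tol_ppm: float = 1.0,
                   constraints: AssignmentConstraints | None = None) -> Formula | None:
    """Best CHONS formula for a negative-mode ion, or None.

    The ion is assumed deprotonated ([M-H]-), so the neutral mass is
    m/z + proton mass.  Candidates are enumerated exhaustively under the
    elemental caps, must have non-negative integer DBE, H/C within
    [hc_min, hc_max] and O/C <= oc_max, and the candidate with the smallest
    absolute mass error wins.  Ties (identical |error| to 1e-4 ppm) are
    broken toward fewer heteroatoms (N+S, then O) and flagged ambiguous.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    con = constraints or AssignmentConstraints()
    neutral = mz + PROTON_MASS
    cand = _candidates(neutral, tol_ppm, con)
    if cand.empty:
        return None
    cand = cand.assign(abs_err=cand["error_ppm"].abs(),
                       hetero=cand["n"] + cand["s"])
    cand = cand.sort_values(["abs_err", "hetero", "o"], kind="stable")
    best = cand.iloc[0]
    ambiguous = bool(len(cand) > 1
                     and cand.iloc[1]["abs_err"] - best["abs_err"] < 1e-4)
    return Formula(
        c=int(best["c"]), h=int(best["h"]), o=int(best["o"]), n=int(best["n"]),
        s=int(best["s"]), neutral_mass=float(best["mass"]),
        error_ppm=float(best["error_ppm"]), dbe=float(best["dbe"]),
        oc=float(best["oc"]), hc=float(best["hc"]), ai=float(best["ai"]),
        has_n=bool(best["n"] > 0), ambiguous=ambiguous,
    )


@dataclass
class CompoundTable:
    """Compounds shared by the inflow and all residual samples.

    ``data`` holds one row per compound: reference m/z, raw intensities
    (``I_inflow``, ``I_res_<label>``), relative intensities (``rI_...``,
    summing to 1 per sample over the shared set) and, once computed,
    ``vf_<label>`` columns of compound-specific mass transfer coefficients
    in cm/h.
    """

    data: pd.DataFrame
    residual_labels: tuple[str, ...]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _match_within_ppm(ref_mz: np.ndarray, sample_mz: np.ndarray,
                      tol_ppm: float) -> np.ndarray:
    """Index into sample_mz of the nearest peak within tol for each ref, else -1."""
    order = np.argsort(sample_mz)
    smz = sample_mz[order]
    pos = np.searchsorted(smz, ref_mz)
    out = np.full(ref_mz.size, -1, dtype=int)
    for i, m in enumerate(ref_mz):
        best, best_d = -1, np.inf
        for j in (pos[i] - 1, pos[i]):
            if 0 <= j < smz.size:
                d = abs(smz[j] - m)
                if d < best_d:
                    best, best_d = j, d
        if best >= 0 and best_d <= m * tol_ppm * 1e-6:
            out[i] = order[best]
    return out


def shared_compound_set(
    inflow: pd.DataFrame,
    residuals: dict[str, pd.DataFrame],
    mz_tol_ppm: float = 1.0,
    intensity_norm: str = "shared_sum",
) -> CompoundTable:
    """Compounds positively identified in the inflow and in every residual.

    ``inflow`` and each residual are peak lists with columns ``mz`` and
    ``intensity``.  Matching is by nearest m/z within a ppm window, so
    unassigned peaks are tracked alongside assigned ones.  Relative
    intensities are computed within each sample over the retained set when
    ``intensity_norm='shared_sum'`` (the relative-availability convention),
    or left as raw intensities with ``'none'``.
    """
    if not residuals:
        raise ValueError("need at least one residual sample")
    if intensity_norm not in ("shared_sum", "none"):
        raise ValueError(f"unknown intensity_norm: {intensity_norm!r}")
    ref_mz = inflow["mz"].to_numpy(dtype=float)
    matches = {}
    keep = np.ones(ref_mz.size, dtype=bool)
    for label, df in residuals.items():
        idx = _match_within_ppm(ref_mz, df["mz"].to_numpy(dtype=float), mz_tol_ppm)
        matches[label] = idx
        keep &= idx >= 0
    if not keep.any():
        raise ValueError("no compound is shared by the inflow and all residuals")
    out = pd.DataFrame({"mz": ref_mz[keep],
                        "I_inflow": inflow["intensity"].to_numpy(dtype=float)[keep]})
    labels = tuple(residuals)
    for label in labels:
        inten = residuals[label]["intensity"].to_numpy(dtype=float)
        out[f"I_res_{label}"] = inten[matches[label][keep]]
    cols = ["I_inflow"] + [f"I_res_{lab}" for lab in labels]
    for col in cols:
        vals = out[col].to_numpy()
        denom = vals.sum() if intensity_norm == "shared_sum" else 1.0
        out["r" + col] = vals / denom
    return CompoundTable(data=out.reset_index(drop=True), residual_labels=labels)


def compound_vf(rI_inflow, rI_residual, h_bar_cm: float, duration_h: float):
    """Compound-specific mass transfer coefficient (cm/h) from intensity ratios.

    ``v_f = (h_bar / T) * ln(rI_inflow / rI_residual)``.  Negative values
    (relative enrichment in the residual pool) are legal and meaningful;
    zero intensities are rejected.
    """
    rI_inflow = np.asarray(rI_inflow, dtype=float)
    rI_residual = np.asarray(rI_residual, dtype=float)
    if duration_h <= 0 or h_bar_cm <= 0:
        raise ValueError("duration and depth equivalent must be positive")
    if np.any(rI_inflow <= 0) or np.any(rI_residual <= 0):
        raise ValueError("intensities must be positive")
    out = (h_bar_cm / duration_h) * np.log(rI_inflow / rI_residual)
    return float(out) if out.ndim == 0 else out


def add_compound_vf(table: CompoundTable, h_bar_cm: float,
                    duration_h: float | dict[str, float]) -> CompoundTable:
    """Attach ``vf_<label>`` columns for every residual sample in the table."""
    df = table.data.copy()
    for label in table.residual_labels:
        T = duration_h[label] if isinstance(duration_h, dict) else duration_h
        df[f"vf_{label}"] = compound_vf(df["rI_inflow"], df[f"rI_res_{label}"],
                                        h_bar_cm, T)
    return CompoundTable(data=df, residual_labels=table.residual_labels)


def doc_pool_diversity(intensities) -> tuple[float, float]:
    """Shannon diversity and evenness of a DOC pool from peak intensities."""
    x = np.asarray(intensities, dtype=float)
    x = x[x > 0]
    if x.size < 2:
        raise ValueError("need at least 2 compounds with signal")
    p = x / x.sum()
    h = float(-np.sum(p * np.log(p)))
    return h, h / float(np.log(x.size))


def van_krevelen(formulas: Sequence[Formula | None],
                 values: Sequence[float] | None = None) -> pd.DataFrame:
    """Plot-ready (O:C, H:C, value) table over the assigned formulas only."""
    rows = []
    for i, f in enumerate(formulas):
        if f is None:
            continue
        rows.append((f.oc, f.hc, float(values[i]) if values is not None else np.nan))
    return pd.DataFrame(rows, columns=["oc", "hc", "value"])
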