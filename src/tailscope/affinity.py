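"""SD:aSD duplex binding free energy and usage-vs-affinity regression.

Two engines compute the hybridization free energy of an SD strand with its
anti-SD partner at 37 degC:

* ``external`` - the ViennaRNA cofold machinery (Python bindings), returning
  the partition-function binding free energy of the two-strand ensemble,
  ΔG = F(AB) - F(A) - F(B), i.e. what ``RNAcofold -a`` prints as
  "delta G binding". This is the default when the bindings are importable.
* ``internal`` - a nearest-neighbor minimum-free-energy duplex model
  (helix stacks + duplex initiation + terminal AU penalties, no loops or
  bulges), whose parameters reproduce the external engine's MFE duplex
  energies exactly for perfect Watson-Crick duplexes. It serves as a
  dependency-free fallback and as a cross-check; for weakly bound AU-rich
  duplexes the ensemble value can sit a few tenths of a kcal/mol below the
  MFE because shifted registers contribute to the partition function.

The relationship between how often an SD sequence is used and its binding
affinity is summarised by an ordinary least squares fit of usage on ΔG with
a quadratic term, the minimal model that can exhibit the interior optimum
("intermediate affinity preferred") reported for these data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "UnpairableError",
    "DuplexEnergy",
    "UsageAffinityFit",
    "duplex_dG",
    "internal_duplex_dG",
    "external_duplex_dG",
    "external_duplex_mfe",
    "have_external_engine",
    "fit_usage_vs_affinity",
    "contrast_heg_leg",
]

# Nearest-neighbor helix parameters at 37 degC (kcal/mol): Watson-Crick
# stacks keyed by the two 5'->3' top-strand bases (the bottom strand is
# their complement), plus duplex initiation and a per-end AU closing
# penalty. Values match the external engine's defaults for perfect
# duplexes (verified by an exact linear solve over random WC duplexes).
_STACK: Dict[str, float] = {
    "AA": -0.9, "AC": -2.2, "AG": -2.1, "AU": -1.1,
    "CA": -2.1, "CC": -3.3, "CG": -2.4, "GA": -2.4,
    "GC": -3.4, "UA": -1.3,
}
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_INIT = 4.10
_TERM_AU = 0.50

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class UnpairableError(ValueError):
    """The two strands cannot form any Watson-Crick helix."""


def _stack_energy(x: str, y: str) -> float:
    """Stack of neighbouring pairs x./y. reading 5'->3' on the top strand."""
    key = x + y
    if key not in _STACK:
        key = _COMP[y] + _COMP[x]
    return _STACK[key]


def _check_rna(s: str, name: str) -> str:
    s = s.upper().replace("T", "U")
    if not re.fullmatch(r"[ACGU]+", s):
        raise ValueError(f"{name} must be RNA over ACGU, got {s!r}")
    return s


def internal_duplex_dG(a: str, b: str) -> float:
    """Best nearest-neighbor helix energy over all ungapped antiparallel registers.

    Considers every contiguous Watson-Crick run formable between the two
    strands and returns the lowest init + stacks + terminal-AU energy.
    Raises :class:`UnpairableError` if no run of at least 2 bp exists.
    """
    a = _check_rna(a, "a")
    b = _check_rna(b, "b")
    n, k = len(a), len(b)
    br = b[::-1]  # antiparallel: a aligns against b read 3'->5'
    best: Optional[float] = None
    for d in range(-(k - 1), n):
        # a[i] faces br[i - d]
        i_lo, i_hi = max(0, d), min(n, k + d)
        run = 0
        for i in range(i_lo, i_hi + 1):
            paired = i < i_hi and (a[i], br[i - d]) in _PAIRS
            if paired:
                run += 1
            elif run:
                if run >= 2:
                    start = i - run
                    e = _INIT
                    for j in range(start, i - 1):
                        e += _stack_energy(a[j], a[j + 1])
                    for end in (a[start], a[i - 1]):
                        if end in "AU":
                            e += _TERM_AU
                    if best is None or e < best:
                        best = e
                run = 0
    if best is None:
        raise UnpairableError("no Watson-Crick helix of >= 2 bp can form")
    return best


def have_external_engine() -> bool:
    try:
        import RNA  # noqa: F401
    except ImportError:
        return False
    return True


def external_duplex_dG(a: str, b: str) -> float:
    """Partition-function binding free energy from the ViennaRNA cofold engine."""
    import RNA

    a = _check_rna(a, "a")
    b = _check_rna(b, "b")
    fc = RNA.fold_compound(f"{a}&{b}")
    # rescale Boltzmann factors around the MFE so deep duplexes keep precision
    _, mfe = fc.mfe_dimer()
    fc.exp_params_rescale(mfe)
    _, f_a, f_b, f_ab, _ = fc.pf_dimer()
    return float(f_ab - f_a - f_b)


def external_duplex_mfe(a: str, b: str) -> float:
    """Minimum free energy intermolecular duplex from the external engine."""
    import RNA

    a = _check_rna(a, "a")
    b = _check_rna(b, "b")
    return float(RNA.duplexfold(a, b).energy)


@dataclass(frozen=True)
class DuplexEnergy:
    sd: str
    partner: str
    dG: float
    engine: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.dG):
            raise ValueError("duplex energy must be finite")


def duplex_dG(a: str, b: str, engine: str = "auto") -> float:
    """Hybridization free energy (kcal/mol, 37 degC) of strands ``a`` and ``b``.

    ``engine`` is ``"external"`` (ViennaRNA ensemble binding energy),
    ``"internal"`` (nearest-neighbor MFE duplex) or ``"auto"`` (external if
    importable, else internal). Both strands must be RNA of length >= 3.
    """
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both strands must be at least 3 nt")
    if engine == "auto":
        engine = "external" if have_external_engine() else "internal"
    if engine == "external":
        return external_duplex_dG(a, b)
    if engine == "internal":
        return internal_duplex_dG(a, b)
    raise ValueError(f"unknown engine {engine!r}")


@dataclass
class UsageAffinityFit:
    """Quadratic OLS of SD usage on duplex ΔG for one gene class."""

    points: pd.DataFrame  # columns sd, usage, dG
    params: np.ndarray  # intercept, linear, quadratic
    r_squared: float
    p_value: float
    opt_dG: Optional[float]
    gene_class: str = "all"

    @property
    def curvature(self) -> float:
        return float(self.params[2])


def fit_usage_vs_affinity(
    points: Union[pd.DataFrame, Sequence[Tuple[str, float, float]]],
    model: str = "quadratic",
    gene_class: str = "all",
) -> UsageAffinityFit:
    """OLS fit of usage counts on ΔG with intercept, linear and quadratic terms.

    ``points`` is a DataFrame with columns (sd, usage, dG) or a sequence of
    such tuples. Reports R², the regression F-test p-value, and the fitted
    optimum -b1/(2 b2) when the curvature is negative (interior maximum).
    """
    if model != "quadratic":
        raise ValueError("only the quadratic model is supported")
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(points, columns=["sd", "usage", "dG"])
    if len(points) < 5:
        raise ValueError("need at least 5 (sd, usage, dG) points")
    dg = points["dG"].to_numpy(dtype=float)
    if np.ptp(dg) == 0:
        raise ValueError("degenerate design: all dG values identical")
    X = sm.add_constant(np.column_stack([dg, dg**2]))
    res = sm.OLS(points["usage"].to_numpy(dtype=float), X).fit()
    b0, b1, b2 = res.params
    opt = float(-b1 / (2 * b2)) if b2 < 0 else None
    if opt is not None and not (dg.min() <= opt <= dg.max()):
        opt = float(np.clip(opt, dg.min(), dg.max()))
    return UsageAffinityFit(
        points=points.reset_index(drop=True),
        params=np.asarray(res.params),
        r_squared=float(res.rsquared),
        p_value=float(res.f_pvalue),
        opt_dG=opt,
        gene_class=gene_class,
    )


@dataclass
class HegLegContrast:
    """Per-SD usage proportions by expression class and peak-sharpness contrast."""

    table: pd.DataFrame  # sd, dG, usage_heg, usage_leg, prop_heg, prop_leg, prop_diff
    sharpness_heg: float
    sharpness_leg: float
    r2_heg: float
    r2_leg: float
    top_sd: str

    @property
    def sharpness_diff(self) -> float:
        return self.sharpness_heg - self.sharpness_leg


def contrast_heg_leg(fit_heg: UsageAffinityFit, fit_leg: UsageAffinityFit) -> HegLegContrast:
    """Contrast SD usage between highly and lowly expressed genes.

    Both fits must cover the same SD set. Reports each SD's usage proportion
    within its class, the per-class |quadratic coefficient| (peak sharpness)
    and R², and flags the SD with the largest HEG-minus-LEG proportion
    difference.
    """
    heg = fit_heg.points.set_index("sd")
    leg = fit_leg.points.set_index("sd")
    if set(heg.index) != set(leg.index):
        raise ValueError("HEG and LEG fits must be over the same SD set")
    leg = leg.loc[heg.index]
    tot_h, tot_l = heg["usage"].sum(), leg["usage"].sum()
    if tot_h == 0:
        raise ValueError("HEG class has zero SD matches")
    if tot_l == 0:
        raise ValueError("LEG class has zero SD matches")
    table = pd.DataFrame(
        {
            "sd": heg.index,
            "dG": heg["dG"].to_numpy(),
            "usage_heg": heg["usage"].to_numpy(),
            "usage_leg": leg["usage"].to_numpy(),
            "prop_heg": heg["usage"].to_numpy() / tot_h,
            "prop_leg": leg["usage"].to_numpy() / tot_l,
        }
    )
    table["prop_diff"] = table["prop_heg"] - table["prop_leg"]
    top_sd = table.loc[table["prop_diff"].idxmax(), "sd"]
    return HegLegContrast(
        table=table.reset_index(drop=True),
        sharpness_heg=abs(fit_heg.curvature),
        sharpness_leg=abs(fit_leg.curvature),
        r2_heg=fit_heg.r_squared,
        r2_leg=fit_leg.r_squared,
        top_sd=str(top_sd),
    )
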