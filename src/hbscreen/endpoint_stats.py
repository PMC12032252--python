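"""Endpoint formulas: tumor volume, T/C ratio, relative readouts,
2^-ddCt expression, and the two-sample Student's t-test.

Caliper tumor volume uses the standard ellipsoid approximation
TV (mm^3) = length * width^2 / 2 with length >= width (longest and
shortest diameters).  qPCR fold changes follow the 2^-ddCt method with a
multi-gene reference: the arithmetic mean of the reference-gene Ct values,
which on the linear scale is exactly the log of their geometric mean.
"""

from __future__ import annotations

import warnings
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "tumor_volume",
    "tc_ratio",
    "ddct_fold",
    "ttest_two",
    "relative_signal",
]

DEFAULT_REFERENCE_GENES = ("Cyclophilin", "GAPDH", "PPIB")


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """TV (mm^3) = length * width^2 / 2; swaps (with a warning) if width > length."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor diameters must be positive")
    if width_mm > length_mm:
        warnings.warn(
            f"width {width_mm} > length {length_mm}: swapping (length is the "
            "longest diameter)",
            stacklevel=2,
        )
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm**2 / 2.0


def tc_ratio(treated_volumes, control_volumes) -> float:
    """Treated-over-control ratio of mean tumor volumes at one timepoint."""
    t = np.asarray(treated_volumes, dtype=float)
    c = np.asarray(control_volumes, dtype=float)
    if t.size < 1 or c.size < 1:
        raise ValueError("need >= 1 animal per group")
    mc = float(c.mean())
    if mc == 0:
        raise ValueError("control group mean volume is zero")
    return float(t.mean()) / mc


def ddct_fold(
    ct: pd.DataFrame,
    target: str,
    treated: str,
    control: str,
    refs: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    gene_col: str = "gene",
    condition_col: str = "condition",
    ct_col: str = "ct",
) -> float:
    """Relative expression of ``target`` in ``treated`` vs ``control``, 2^-ddCt.

    dCt(condition) = mean Ct_target - mean over refs of (mean Ct_ref);
    fold = 2 ** -(dCt_treated - dCt_control).  Replicate Ct values are
    averaged per gene and condition.  Adding a constant to every Ct (a
    plate offset) leaves the fold change unchanged.
    """
    if not np.all(np.isfinite(ct[ct_col])) or (ct[ct_col] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    means = ct.groupby([condition_col, gene_col])[ct_col].mean()

    def dct(cond: str) -> float:
        if (cond, target) not in means.index:
            raise ValueError(f"target gene {target!r} not measured in {cond!r}")
        ref_cts = []
        for g in refs:
            if (cond, g) not in means.index:
                raise ValueError(f"reference gene {g!r} not measured in {cond!r}")
            ref_cts.append(means[(cond, g)])
        return float(means[(cond, target)] - np.mean(ref_cts))

    return float(2.0 ** -(dct(treated) - dct(control)))


def ttest_two(a, b, equal_var: bool = True) -> dict[str, float]:
    """Two-sided two-sample t-test (Student's pooled-variance by default).

    Returns {'t', 'df', 'p'}.  Identical constant groups define t = 0,
    p = 1 rather than 0/0.  Welch's form is available via
    ``equal_var=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = sqrt(va / na + vb / nb)
        df = (
            (va / na + vb / nb) ** 2
            / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            if va + vb > 0 else na + nb - 2
        )
    if se == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
    else:
        t = float(diff / se)
    p = 1.0 if t == 0 else float(2.0 * sps.t.sf(abs(t), df))
    return {"t": t, "df": float(df), "p": p}


def relative_signal(treated, control) -> dict[str, float]:
    """Treated/control mean-readout fraction and the percent decrease."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if c.size < 1 or float(c.mean()) <= 0:
        raise ValueError("control mean must be positive")
    frac = float(t.mean()) / float(c.mean())
    return {"fraction": frac, "percent_decrease": 100.0 * (1.0 - frac)}
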