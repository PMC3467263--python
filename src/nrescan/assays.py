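"""Quantification formulas for the downstream wet-lab readouts.

Covers the standard relative-quantification arithmetic used to validate
screen candidates: ddCt fold changes for RT-qPCR normalised to a
housekeeping gene, relative luciferase activity (firefly/Renilla) and fold
induction for reporter assays, exact-match in-silico PCR product sizing, and
the unpaired Student t-test with the conventional significance stars
(* p<0.05, ** p<0.01, *** p<0.001).

ddCt convention: dCt = Ct_target - Ct_housekeeping per sample;
ddCt = dCt_sample - mean(dCt of the control group); fold = 2**(-ddCt).
The control group's folds are computed the same way, so the control *mean
dCt* is the reference — individual control folds equal 1 only when all
control dCt values coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import reverse_complement

__all__ = [
    "CtMeasurement",
    "LuciferaseWell",
    "PrimerPair",
    "PcrProduct",
    "TestResult",
    "ddct_fold",
    "rla_fold",
    "insilico_pcr",
    "unpaired_t",
    "stars_for",
]

_BASES = set("ACGT")


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    group: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise ValueError(f"sample {self.sample_id}: Ct must be > 0")


@dataclass(frozen=True)
class LuciferaseWell:
    well_id: str
    condition: str
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.firefly < 0:
            raise ValueError(f"well {self.well_id}: firefly signal must be >= 0")
        if not self.renilla > 0:
            raise ValueError(f"well {self.well_id}: Renilla signal must be > 0")

    @property
    def rla(self) -> float:
        """Relative luciferase activity: firefly normalised to Renilla."""
        return self.firefly / self.renilla


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or set(p.upper()) - _BASES:
                raise ValueError(f"{name} primer must be nonempty A/C/G/T")


@dataclass(frozen=True)
class PcrProduct:
    start: int  # 0-based start of forward-primer footprint
    end: int    # 0-based exclusive end of reverse-primer footprint

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    stars: str


def _as_ct_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    return pd.DataFrame(
        [
            {"sample_id": m.sample_id, "group": m.group, "gene": m.gene, "ct": m.ct}
            for m in measurements
        ]
    )


def ddct_fold(
    measurements,
    target: str,
    housekeeping: str,
    control_group: str,
):
    """Per-sample ddCt fold changes plus per-group mean and SEM.

    ``measurements`` is a DataFrame (sample_id, group, gene, ct) or a list of
    CtMeasurement; each sample needs one target and one housekeeping Ct.
    Returns ``(per_sample, summary)`` DataFrames; summary carries
    mean_fold, sem_fold (n-1 denominator variance) and n per group.
    """
    df = _as_ct_frame(measurements)
    wide = {}
    for sid, sub in df.groupby("sample_id"):
        cts = dict(zip(sub["gene"], sub["ct"]))
        if target not in cts:
            raise ValueError(f"sample {sid}: missing target ({target}) Ct")
        if housekeeping not in cts:
            raise ValueError(f"sample {sid}: missing housekeeping ({housekeeping}) Ct")
        wide[sid] = (sub["group"].iloc[0], cts[target] - cts[housekeeping])
    per = pd.DataFrame(
        [(sid, grp, dct) for sid, (grp, dct) in wide.items()],
        columns=["sample_id", "group", "delta_ct"],
    )
    control = per.loc[per["group"] == control_group, "delta_ct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    per["ddct"] = per["delta_ct"] - control.mean()
    per["fold"] = 2.0 ** (-per["ddct"])
    summary = (
        per.groupby("group")["fold"]
        .agg(mean_fold="mean", sem_fold=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return per, summary


def rla_fold(wells, treated_label: str, control_label: str) -> float:
    """Fold induction: mean RLA of treated wells over mean RLA of control wells."""
    by = {}
    for w in wells:
        by.setdefault(w.condition, []).append(w.rla)
    for label in (treated_label, control_label):
        if label not in by:
            raise ValueError(f"no wells with condition {label!r}")
    return float(np.mean(by[treated_label]) / np.mean(by[control_label]))


def insilico_pcr(template: str, primers: PrimerPair) -> list[PcrProduct]:
    """Exact-match PCR products of a primer pair on a template.

    A product spans each forward-primer match to each downstream exact match
    of the reverse complement of the reverse primer, inclusive of both primer
    footprints.  No product is not an error: returns an empty list.
    """
    t = template.upper()
    fwd = primers.forward.upper()
    rev_site = reverse_complement(primers.reverse)

    def all_matches(s: str, sub: str) -> list[int]:
        out, i = [], s.find(sub)
        while i != -1:
            out.append(i)
            i = s.find(sub, i + 1)
        return out

    products = []
    rev_starts = all_matches(t, rev_site)
    for f in all_matches(t, fwd):
        for r in rev_starts:
            if r >= f + len(fwd):
                products.append(PcrProduct(start=f, end=r + len(rev_site)))
    products.sort(key=lambda p: (p.start, p.end))
    return products


def stars_for(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def unpaired_t(group_a, group_b, welch: bool = False) -> TestResult:
    """Two-sided unpaired t-test (pooled variance by default, Welch optional).

    Degenerate zero-variance inputs: equal means give t=0, p=1; unequal means
    leave the statistic undefined and raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult(t=0.0, p=1.0, stars="ns")
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(t=float(t), p=float(p), stars=stars_for(float(p)))
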