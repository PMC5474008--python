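"""Efficiency-corrected relative qPCR quantification with randomization testing.

The relative expression ratio follows the classic efficiency-corrected
formulation: ratio = E_target^dCq_target / E_ref^dCq_ref, with dCq the mean
quantification-cycle shift between control and sample conditions.  The
significance test permutes condition labels within each gene and compares
|log ratio| against the observed value, with a plus-one correction so p is
never exactly zero.  Amplification efficiency E is an input (as produced by
fluorescence-curve analysis tools) in (1, 2], 2 meaning perfect doubling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrWell:
    target: str
    condition: str   # "sample" | "control"
    replicate: int
    cq: float
    efficiency: float

    def __post_init__(self) -> None:
        if not (self.cq > 0 and math.isfinite(self.cq)):
            raise QpcrError(f"{self.target}: Cq must be finite and > 0")
        if not (1.0 < self.efficiency <= 2.0):
            raise QpcrError(
                f"{self.target}: efficiency {self.efficiency} outside (1, 2]"
            )


@dataclass(frozen=True)
class ExpressionRatio:
    target: str
    reference: str
    ratio: float
    sd: float              # delta-method propagation of replicate Cq SDs
    sd_replicate: float    # SD of replicate-wise ratios (alternative convention)
    p_value: float
    n_randomizations: int


def wells_from_tsv(path: str | Path) -> list[QpcrWell]:
    df = pd.read_csv(path, sep="\t")
    return [
        QpcrWell(str(r.target), str(r.condition), int(r.replicate),
                 float(r.cq), float(r.efficiency))
        for r in df.itertuples()
    ]


def _gene_wells(wells: Sequence[QpcrWell], target: str) -> dict[str, list[QpcrWell]]:
    by_cond: dict[str, list[QpcrWell]] = {"sample": [], "control": []}
    for w in wells:
        if w.target == target:
            by_cond.setdefault(w.condition, []).append(w)
    for cond in ("sample", "control"):
        if len(by_cond[cond]) < 2:
            raise QpcrError(f"{target}: need >= 2 replicates in condition {cond!r}")
    return by_cond


def _mean_efficiency(ws: Iterable[QpcrWell]) -> float:
    vals = [w.efficiency for w in ws]
    return float(np.mean(vals))


def _log_ratio(cq_t_s, cq_t_c, cq_r_s, cq_r_c, e_t: float, e_r: float) -> float:
    """log of the efficiency-corrected ratio at replicate means."""
    d_t = float(np.mean(cq_t_c)) - float(np.mean(cq_t_s))
    d_r = float(np.mean(cq_r_c)) - float(np.mean(cq_r_s))
    return d_t * math.log(e_t) - d_r * math.log(e_r)


def relative_ratio(
    wells: Sequence[QpcrWell],
    target: str,
    reference: str,
    n_randomizations: int = 2000,
    seed: int | None = 0,
) -> ExpressionRatio:
    """Efficiency-corrected expression ratio of target vs reference.

    dCq = mean Cq(control) - mean Cq(sample) per gene; the ratio is
    E_t^dCq_t / E_r^dCq_r.  ``sd`` propagates the replicate Cq standard
    deviations through the log-ratio by the delta method; ``sd_replicate``
    is the SD of replicate-paired ratios.  The p-value comes from the
    within-gene label randomization test.
    """
    tw = _gene_wells(wells, target)
    rw = _gene_wells(wells, reference)
    e_t, e_r = _mean_efficiency(tw["sample"] + tw["control"]), \
        _mean_efficiency(rw["sample"] + rw["control"])
    cq = {
        (g, c): np.array([w.cq for w in ws[c]])
        for g, ws in (("t", tw), ("r", rw))
        for c in ("sample", "control")
    }
    logr = _log_ratio(cq[("t", "sample")], cq[("t", "control")],
                      cq[("r", "sample")], cq[("r", "control")], e_t, e_r)
    ratio = math.exp(logr)
    # delta method on the log scale: var(logR) = sum over the four groups
    var_log = 0.0
    for (g, c), arr in cq.items():
        e = e_t if g == "t" else e_r
        var_log += (math.log(e) ** 2) * arr.var(ddof=1) / len(arr)
    sd = ratio * math.sqrt(var_log)
    # replicate-paired ratios (technical triplicate convention)
    n_pair = min(len(cq[("t", "sample")]), len(cq[("t", "control")]),
                 len(cq[("r", "sample")]), len(cq[("r", "control")]))
    rep_ratios = [
        math.exp(_log_ratio(cq[("t", "sample")][i : i + 1], cq[("t", "control")][i : i + 1],
                            cq[("r", "sample")][i : i + 1], cq[("r", "control")][i : i + 1],
                            e_t, e_r))
        for i in range(n_pair)
    ]
    sd_rep = float(np.std(rep_ratios, ddof=1)) if n_pair > 1 else float("nan")
    p = randomization_test(wells, target, reference, n=n_randomizations, seed=seed)
    return ExpressionRatio(target, reference, ratio, sd, sd_rep, p, n_randomizations)


def randomization_test(
    wells: Sequence[QpcrWell],
    target: str,
    reference: str,
    n: int = 2000,
    seed: int | None = 0,
) -> float:
    """Two-sided permutation p-value for the log expression ratio.

    Condition labels are permuted within each gene; p = (b + 1) / (n + 1)
    where b counts permutations with |log ratio| >= the observed one.
    """
    if n < 100:
        warnings.warn(f"n={n} randomizations is low; p-value resolution is coarse")
    tw = _gene_wells(wells, target)
    rw = _gene_wells(wells, reference)
    e_t = _mean_efficiency(tw["sample"] + tw["control"])
    e_r = _mean_efficiency(rw["sample"] + rw["control"])
    t_all = np.array([w.cq for w in tw["sample"] + tw["control"]])
    r_all = np.array([w.cq for w in rw["sample"] + rw["control"]])
    nt_s, nr_s = len(tw["sample"]), len(rw["sample"])
    observed = abs(_log_ratio(t_all[:nt_s], t_all[nt_s:], r_all[:nr_s], r_all[nr_s:],
                              e_t, e_r))
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n):
        tp = rng.permutation(t_all)
        rp = rng.permutation(r_all)
        stat = abs(_log_ratio(tp[:nt_s], tp[nt_s:], rp[:nr_s], rp[nr_s:], e_t, e_r))
        if stat >= observed - 1e-12:
            b += 1
    return (b + 1) / (n + 1)


def rhapa_quantify(
    wells: Sequence[QpcrWell],
    amplicons: Sequence[str],
    reference: str,
    comparator: str | None = None,
    n_randomizations: int = 2000,
    seed: int | None = 0,
) -> list[ExpressionRatio]:
    """Relative abundance of APA amplicons after RNase-H removal of full-length 3' ends.

    Each amplicon (a qPCR target tiled along the alternatively polyadenylated
    gene) is expressed relative to the cleaved-off 3'-most amplicon (the
    comparator, by default the last amplicon listed), normalized by the
    reference gene within each condition.  Wells for all amplicons, measured
    on the same cDNA, carry condition "sample"; a second biological condition
    may be present and is quantified identically.
    """
    comparator = comparator or amplicons[-1]
    targets = {w.target for w in wells}
    if comparator not in targets:
        raise QpcrError(f"comparator amplicon {comparator!r} has no wells")
    missing = [a for a in amplicons if a not in targets]
    if missing:
        raise QpcrError(f"amplicon(s) without wells: {missing}")
    if reference not in targets:
        raise QpcrError(f"reference {reference!r} has no wells")
    conditions = sorted({w.condition for w in wells})
    out: list[ExpressionRatio] = []
    for a in amplicons:
        if a == comparator:
            continue
        for cond in conditions:
            # recast within-condition amplicon-vs-comparator contrast as a
            # sample/control pair so the ratio machinery applies unchanged
            recast: list[QpcrWell] = []
            for w in wells:
                if w.condition != cond:
                    continue
                if w.target == a:
                    recast.append(QpcrWell(a, "sample", w.replicate, w.cq, w.efficiency))
                elif w.target == comparator:
                    recast.append(QpcrWell(a, "control", w.replicate, w.cq, w.efficiency))
            # the reference is measured once per condition: duplicate it into
            # both pseudo-conditions so its dCq is 0 and it cancels exactly
            ref_wells = [w for w in wells if w.target == reference and w.condition == cond]
            for w in ref_wells:
                recast.append(QpcrWell(reference, "sample", w.replicate, w.cq, w.efficiency))
                recast.append(QpcrWell(reference, "control", w.replicate, w.cq, w.efficiency))
            r = relative_ratio(recast, a, reference,
                               n_randomizations=n_randomizations, seed=seed)
            label = a if len(conditions) == 1 else f"{a}[{cond}]"
            out.append(ExpressionRatio(label, reference, r.ratio, r.sd,
                                       r.sd_replicate, r.p_value, r.n_randomizations))
    return out


def ratios_to_tsv(ratios: Sequence[ExpressionRatio], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target\treference\tratio\tsd\tsd_replicate\tp_value\tn_randomizations\n")
        for r in ratios:
            fh.write(
                f"{r.target}\t{r.reference}\t{r.ratio:.6g}\t{r.sd:.6g}\t"
                f"{r.sd_replicate:.6g}\t{r.p_value:.6g}\t{r.n_randomizations}\n"
            )
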