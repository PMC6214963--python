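"""Two-library differential expression of miRNA read counts.

Counts are normalized to reads per million (RPM) of each library's clean-read
total; a normalized value of zero is replaced by 0.01 so fold changes stay
finite. The fold change is log2(RPM_BR / RPM_BS), so positive values mean
higher expression in the browning-resistant (BR) library. Significance uses
the Audic–Claverie exact conditional test for comparing one tag's counts
between two libraries of known depths:

    P(Y = y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

which is the negative-binomial law NB(r = x+1, p = N1/(N1+N2)) in y; the
implementation uses that identity, evaluated by scipy in log space. The
default p-value is two-sided by tail doubling, capped at 1. miRNAs with RPM
below 1 in both libraries are skipped as too scarce to test. No
multiple-testing correction is applied to calls; a Benjamini–Hochberg column
is emitted for reference only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st

PSEUDO_EXPR = 0.01


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-miRNA expression comparison between the two libraries."""

    mirna_id: str
    x: int          # reads in BR
    y: int          # reads in BS
    N1: int         # BR clean-read total
    N2: int         # BS clean-read total
    rpm_BR: float
    rpm_BS: float
    fc: float       # log2(rpm_BR / rpm_BS)
    p: float
    call: str       # up | down | ns | skipped_low
    fdr: float | None = None


def normalize_rpm(count: int, libsize: int) -> float:
    """Reads-per-million; exact zeros become the 0.01 pseudo-expression."""
    if libsize <= 0:
        raise ValueError("libsize must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    rpm = count * 1e6 / libsize
    return PSEUDO_EXPR if rpm == 0 else rpm


def ac_pvalue(x: int, y: int, N1: int, N2: int, two_sided: bool = True) -> float:
    """Audic–Claverie p-value for observing ``y`` given ``x``.

    Two-sided by doubling the smaller tail, capped at 1; one-sided returns
    the smaller tail itself.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    p_success = N1 / (N1 + N2)
    lower = float(_st.nbinom.cdf(y, x + 1, p_success))       # P(Y <= y | x)
    upper = float(_st.nbinom.sf(y - 1, x + 1, p_success))    # P(Y >= y | x)
    tail = min(lower, upper)
    return min(1.0, 2.0 * tail) if two_sided else min(1.0, tail)


def ac_pvalue_bruteforce(x: int, y: int, N1: int, N2: int,
                         two_sided: bool = True) -> float:
    """Independent oracle: direct log-space summation of P(Y=y'|x)."""
    from scipy.special import gammaln

    ys = np.arange(0, max(4 * (x + y + 10), 2000))
    ratio = N2 / N1
    logp = (
        ys * np.log(ratio)
        + gammaln(x + ys + 1) - gammaln(x + 1) - gammaln(ys + 1)
        - (x + ys + 1) * np.log1p(ratio)
    )
    probs = np.exp(logp)
    lower = probs[: y + 1].sum()
    upper = probs[y:].sum()
    tail = min(lower, upper)
    return min(1.0, 2.0 * tail) if two_sided else min(1.0, float(tail))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def call_differential(
    records: Mapping[str, tuple[int, int]],
    N1: int,
    N2: int,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
    two_sided: bool = True,
) -> list[DiffExprRecord]:
    """Normalize, test, and call each miRNA up/down/ns/skipped_low.

    ``records`` maps miRNA id -> (reads_BR, reads_BS). miRNAs with RPM < 1
    in both libraries are skipped before testing.
    """
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    out: list[DiffExprRecord] = []
    tested_idx: list[int] = []
    for mid in sorted(records):
        x, y = records[mid]
        rpm_br = normalize_rpm(x, N1)
        rpm_bs = normalize_rpm(y, N2)
        fc = float(np.log2(rpm_br / rpm_bs))
        if rpm_br < 1 and rpm_bs < 1:
            out.append(DiffExprRecord(mid, x, y, N1, N2, rpm_br, rpm_bs,
                                      fc, 1.0, "skipped_low"))
            continue
        p = ac_pvalue(x, y, N1, N2, two_sided)
        if p <= p_cut and fc >= fc_cut:
            call = "up"
        elif p <= p_cut and fc <= -fc_cut:
            call = "down"
        else:
            call = "ns"
        tested_idx.append(len(out))
        out.append(DiffExprRecord(mid, x, y, N1, N2, rpm_br, rpm_bs,
                                  fc, p, call))
    if tested_idx:
        adj = bh_fdr([out[i].p for i in tested_idx])
        for j, i in enumerate(tested_idx):
            r = out[i]
            out[i] = DiffExprRecord(r.mirna_id, r.x, r.y, r.N1, r.N2,
                                    r.rpm_BR, r.rpm_BS, r.fc, r.p, r.call,
                                    float(adj[j]))
    return out


def diffexpr_tsv(records: Sequence[DiffExprRecord]) -> str:
    lines = ["miRNA\treads_BR\treads_BS\trpm_BR\trpm_BS\tlog2_fc\tp_value\tfdr\tcall"]
    for r in records:
        fdr = "" if r.fdr is None else f"{r.fdr:.6g}"
        lines.append(
            f"{r.mirna_id}\t{r.x}\t{r.y}\t{r.rpm_BR:.4f}\t{r.rpm_BS:.4f}\t"
            f"{r.fc:.4f}\t{r.p:.6g}\t{fdr}\t{r.call}"
        )
    return "\n".join(lines) + "\n"
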