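"""Independent brute-force oracles used to validate the catalog builder
and the read scanner on small inputs.  These deliberately avoid the
package's index/matcher machinery: absence is tested by naive substring
search of the reference (both strands), and read scanning is a double
loop over reads x catalog sequences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def canon(seq: str) -> str:
    r = rc(seq)
    return seq if seq <= r else r


def naive_windows(reference: str, pos1: int, alt: str, k: int) -> set[str]:
    """All k-windows covering 1-based position pos1 with alt substituted."""
    p = pos1 - 1
    out = set()
    for start in range(max(0, p - k + 1), min(len(reference) - k, p) + 1):
        w = reference[start : start + k]
        cand = w[: p - start] + alt + w[p - start + 1 :]
        if set(cand) <= set("ACGT"):
            out.add(cand)
    return out


def naive_catalog(
    recurrent: pd.DataFrame,
    population: pd.DataFrame,
    reference: str,
    k: int,
    af_threshold: float = 0.0,
) -> set[str]:
    """Canonical neomer set by exhaustive substring search."""
    ref_fwd = reference
    ref_rev = rc(reference)

    def absent(seq: str) -> bool:
        return seq not in ref_fwd and seq not in ref_rev

    pop_kmers: set[str] = set()
    for _, row in population.iterrows():
        if "af" in population.columns and row["af"] < af_threshold:
            continue
        for w in naive_windows(reference, int(row["pos"]), row["alt"], k):
            pop_kmers.add(canon(w))

    result: set[str] = set()
    for _, row in recurrent.iterrows():
        assert reference[int(row["pos"]) - 1] == row["ref"]
        for w in naive_windows(reference, int(row["pos"]), row["alt"], k):
            if absent(w) and canon(w) not in pop_kmers:
                result.add(canon(w))
    return result


def naive_profile(
    reads: list[str], catalog_sequences: list[str]
) -> tuple[int, np.ndarray]:
    """(neomer_reads, per-neomer read counts) by double-loop search."""
    counts = np.zeros(len(catalog_sequences), dtype=int)
    neomer_reads = 0
    for read in reads:
        read_rc = rc(read)
        hit_any = False
        for i, seq in enumerate(catalog_sequences):
            if seq in read or seq in read_rc:
                counts[i] += 1
                hit_any = True
        if hit_any:
            neomer_reads += 1
    return neomer_reads, counts


def cox_hr_grid(time, event, group, betas=None) -> float:
    """1-parameter Cox partial-likelihood maximization on a grid (Efron
    ties), as an oracle for the binary-covariate hazard ratio."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(group, dtype=float)
    if betas is None:
        betas = np.linspace(-5, 5, 20001)

    def log_pl(beta: float) -> float:
        ll = 0.0
        for t in np.unique(time[event]):
            d_idx = np.flatnonzero(event & (time == t))
            risk = np.flatnonzero(time >= t)
            theta = np.exp(beta * x)
            sum_risk = theta[risk].sum()
            sum_d = theta[d_idx].sum()
            m = len(d_idx)
            ll += beta * x[d_idx].sum()
            for ell in range(m):
                ll -= np.log(sum_risk - (ell / m) * sum_d)
        return ll

    values = [log_pl(b) for b in betas]
    return float(np.exp(betas[int(np.argmax(values))]))
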