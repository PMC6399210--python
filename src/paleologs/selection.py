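"""Counting-method Ka/Ks on codon pairs and likelihood-ratio-test bookkeeping.

Ka/Ks (omega) is estimated with the Nei-Gojobori (1986) counting method:

* per-codon synonymous site fractions are computed from the genetic code
  (each of the nine single-nucleotide neighbours contributes 1/3 of a site;
  changes creating a stop codon count as non-synonymous), averaged over the
  two sequences, so N + S = 3 x compared codons exactly;
* codons differing at k positions are resolved by averaging synonymous /
  non-synonymous step counts over all k! orderings of single-nucleotide
  steps, skipping pathways that pass through stop codons;
* proportions pN = Nd/N and pS = Sd/S receive the Jukes-Cantor multiple-hit
  correction  K = -(3/4) ln(1 - (4/3) p).

The LRT layer is bookkeeping over externally supplied log-likelihoods of
nested codon models: the statistic is 2 x |lnl1 - lnl0|, compared either to
chi-square upper-tail probabilities or to the critical values of the 50:50
mixture of a point mass at zero and chi-square with 1 df (2.71 at 5%,
5.41 at 1%) appropriate for boundary null hypotheses such as branch-site
tests of positive selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy.stats import chi2

__all__ = [
    "KaKsResult",
    "LrtResult",
    "ng86_kaks",
    "lrt",
    "mixture_critical_value",
    "read_codon_pair_fasta",
    "kaks_table",
    "lrt_table",
    "SaturationError",
]

NUCLEOTIDES = "ACGT"


class SaturationError(ValueError):
    """Jukes-Cantor correction undefined: (4/3) p >= 1."""


def _codon_map(code_id: int = 1) -> dict[str, str]:
    """codon -> amino acid (stops as '*') for an NCBI genetic code id."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def _syn_fraction(codon: str, aa_of: dict[str, str]) -> float:
    """Synonymous site count of one sense codon (0..3).

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes to stop codons are non-synonymous.
    """
    total = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if aa_of[alt] != "*" and aa_of[alt] == aa_of[codon]:
                syn += 1
        total += syn / 3.0
    return total


def _pathway_differences(
    codon_a: str, codon_b: str, aa_of: dict[str, str]
) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two sense codons.

    Averages over all orderings of the single-nucleotide steps from a to b.
    Pathways through stop codons are skipped; if every pathway is blocked
    (possible only for 3-fold differences) all pathways are used with the
    stop treated as its own "amino acid".
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        current = codon_a
        syn = non = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if aa_of[nxt] == "*" and not allow_stops:
                return None
            if aa_of[nxt] == aa_of[current]:
                syn += 1
            else:
                non += 1
            current = nxt
        return syn, non

    paths = [walk(order, False) for order in permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(diff_positions)]
    syn = sum(p[0] for p in valid) / len(valid)
    non = sum(p[1] for p in valid) / len(valid)
    return syn, non


def _jukes_cantor(p: float) -> float:
    if p == 0:
        return 0.0
    x = 1.0 - (4.0 / 3.0) * p
    if x <= 0:
        raise SaturationError(f"proportion {p:.4f} saturates the Jukes-Cantor correction")
    return -0.75 * math.log(x)


@dataclass
class KaKsResult:
    """Nei-Gojobori site and difference counts with corrected rates.

    ``ka`` / ``ks`` are None when the Jukes-Cantor correction saturates;
    ``omega`` is None when Ks is zero or either rate is undefined (flagged
    in ``omega_defined``).
    """

    n_sites: float  # N: average non-synonymous sites
    s_sites: float  # S: average synonymous sites
    n_diffs: float  # Nd
    s_diffs: float  # Sd
    codons_compared: int
    codons_excluded: int
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    omega: float | None

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


def _clean_codons(
    seq_a: str, seq_b: str, aa_of: dict[str, str]
) -> tuple[list[tuple[str, str]], int]:
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    kept: list[tuple[str, str]] = []
    excluded = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        ok = all(nt in NUCLEOTIDES for nt in ca + cb)
        if ok and aa_of[ca] != "*" and aa_of[cb] != "*":
            kept.append((ca, cb))
        else:
            excluded += 1
    return kept, excluded


def ng86_kaks(seq_a: str, seq_b: str, code_id: int = 1) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for one pairwise codon alignment.

    Codons containing gaps or ambiguity characters, or that are stop codons
    in either sequence, are excluded pairwise.  Symmetric in its two
    arguments.  Raises :class:`ValueError` when no codon survives filtering.
    """
    aa_of = _codon_map(code_id)
    pairs, excluded = _clean_codons(seq_a, seq_b, aa_of)
    if not pairs:
        raise ValueError("no comparable codons after filtering")

    s_sites = sum(_syn_fraction(ca, aa_of) + _syn_fraction(cb, aa_of) for ca, cb in pairs) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    s_diffs = n_diffs = 0.0
    for ca, cb in pairs:
        syn, non = _pathway_differences(ca, cb, aa_of)
        s_diffs += syn
        n_diffs += non

    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    try:
        ka = _jukes_cantor(pn)
    except SaturationError:
        ka = None
    if s_sites == 0:
        ks = None
    else:
        try:
            ks = _jukes_cantor(ps)
        except SaturationError:
            ks = None
    omega = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(
        n_sites=n_sites,
        s_sites=s_sites,
        n_diffs=n_diffs,
        s_diffs=s_diffs,
        codons_compared=len(pairs),
        codons_excluded=excluded,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        omega=omega,
    )


def mixture_critical_value(alpha: float) -> float:
    """Upper-alpha critical value of the 1/2 chi2(0) + 1/2 chi2(1) mixture.

    This is the null for LRTs whose parameter sits on the boundary under
    the null (e.g. branch-site positive-selection tests): half the mass is
    a point mass at zero, so for alpha < 1/2 the threshold is the
    chi-square(1 df) quantile at 1 - 2 alpha; for alpha >= 1/2 it is 0.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if alpha >= 0.5:
        return 0.0
    return float(chi2.ppf(1.0 - 2.0 * alpha, df=1))


@dataclass
class LrtResult:
    """Likelihood-ratio statistic and significance call.

    ``significance`` is "1%", "5%" or "ns"; a 1% call implies the 5% one.
    ``p`` is the chi-square upper-tail probability when a df was supplied,
    else the mixture-distribution tail probability.
    """

    lnl_alt: float
    lnl_null: float
    statistic: float
    significance: str
    p: float | None = None


def lrt(
    lnl_alt: float,
    lnl_null: float,
    null_kind: str = "mixture",
    df: int | None = None,
) -> LrtResult:
    """Likelihood-ratio test statistic 2 x |lnl_alt - lnl_null|.

    ``null_kind="mixture"`` calls significance against the boundary-mixture
    critical values (2.71 at 5%, 5.41 at 1%); ``null_kind="chisq"`` uses the
    chi-square upper tail at the supplied ``df``.
    """
    if not (math.isfinite(lnl_alt) and math.isfinite(lnl_null)):
        raise ValueError("log-likelihoods must be finite")
    statistic = 2.0 * abs(lnl_alt - lnl_null)
    if null_kind == "mixture":
        p = 0.5 * float(chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
        if statistic >= mixture_critical_value(0.01):
            call = "1%"
        elif statistic >= mixture_critical_value(0.05):
            call = "5%"
        else:
            call = "ns"
        return LrtResult(lnl_alt, lnl_null, statistic, call, p)
    if null_kind == "chisq":
        if df is None or df < 1:
            raise ValueError("chisq null requires df >= 1")
        p = float(chi2.sf(statistic, df=df))
        call = "1%" if p <= 0.01 else "5%" if p <= 0.05 else "ns"
        return LrtResult(lnl_alt, lnl_null, statistic, call, p)
    raise ValueError(f"unknown null_kind {null_kind!r}; use 'mixture' or 'chisq'")


def read_codon_pair_fasta(path: str | Path) -> tuple[str, str]:
    """Read a two-record aligned FASTA into a codon pair."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    return str(records[0].seq), str(records[1].seq)


def kaks_table(
    pairs: Iterable[tuple[str, tuple[str, str]]], code_id: int = 1
) -> pd.DataFrame:
    """Batch NG86 over named codon pairs -> tidy DataFrame."""
    rows = []
    for name, (a, b) in pairs:
        r = ng86_kaks(a, b, code_id=code_id)
        rows.append(
            {
                "pair": name,
                "N": r.n_sites,
                "S": r.s_sites,
                "Nd": r.n_diffs,
                "Sd": r.s_diffs,
                "pN": r.pn,
                "pS": r.ps,
                "Ka": r.ka,
                "Ks": r.ks,
                "omega": r.omega,
                "codons": r.codons_compared,
                "excluded": r.codons_excluded,
            }
        )
    return pd.DataFrame(rows)


def lrt_table(
    table: pd.DataFrame, null_kind: str = "mixture", df: int | None = None
) -> pd.DataFrame:
    """Apply :func:`lrt` to a table with columns branch, lnl_alt, lnl_null."""
    required = {"branch", "lnl_alt", "lnl_null"}
    if not required.issubset(table.columns):
        raise ValueError(f"LRT table needs columns {sorted(required)}")
    rows = []
    for row in table.itertuples():
        res = lrt(row.lnl_alt, row.lnl_null, null_kind=null_kind, df=df)
        rows.append(
            {
                "branch": row.branch,
                "lnl_alt": res.lnl_alt,
                "lnl_null": res.lnl_null,
                "statistic": res.statistic,
                "significance": res.significance,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
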