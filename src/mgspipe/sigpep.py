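"""Signal-peptide calls and with/without ratio statistics.

Secretion of an enzyme requires an N-terminal Sec signal peptide; the
fraction of proteins carrying one is the secretion statistic compared
between groups (e.g. an environmental gene set versus a reference set).
Production analyses ingest an external predictor's calls from TSV; for
synthetic ground-truth testing a deterministic heuristic caller is
provided.  The heuristic is an explicit stand-in — a classical
n/h/c-region rule, not a reimplementation of any trained predictor:

* **n-region** — net charge of residues 2–6 at least +1 (K/R minus D/E);
* **h-region** — some 7-residue window within residues 3–25 with mean
  Kyte–Doolittle hydropathy ≥ 1.6;
* **c-region** — an A-X-A-style cleavage site at position 15–45 with the
  −3 and −1 residues small and neutral (A, G, S, C or T).

Group differences are tested on the 2×2 with/without table by chi-square
with continuity correction, substituting Fisher's exact test when any
expected cell count is below 5 or a margin is zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from mgspipe.errors import MgsConfigError, MgsDataError

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SMALL_NEUTRAL = set("AGSCT")

MIN_LENGTH = 15
MAX_SP_REGION = 45
MIN_CLEAVAGE = 15
HYDROPATHY_WINDOW = 7
HYDROPATHY_MIN = 1.6


@dataclass(frozen=True)
class SignalPeptideCall:
    """Per-protein call; cleavage position is the 1-based index of the last
    signal-peptide residue and is present only when ``has_sp``."""

    protein_id: str
    group: str
    has_sp: bool
    cleavage_position: int | None = None

    def __post_init__(self) -> None:
        if self.cleavage_position is not None and not self.has_sp:
            raise MgsDataError(
                f"{self.protein_id}: cleavage position without a signal peptide"
            )


def call_signal_peptide(
    protein: str, protein_id: str = "", group: str = ""
) -> SignalPeptideCall:
    """Heuristic Sec signal-peptide call on an amino-acid sequence.

    Proteins shorter than 15 residues or not starting with M are
    automatically negative.  Otherwise all three region rules (charge,
    hydropathy, cleavage site) must hold within the first 45 residues;
    the cleavage position is the first valid site.
    """
    seq = protein.upper()
    bad = set(seq) - set(KYTE_DOOLITTLE)
    if bad:
        raise MgsDataError(f"{protein_id or 'protein'}: non-amino-acid characters {sorted(bad)}")
    if len(seq) < MIN_LENGTH or not seq.startswith("M"):
        return SignalPeptideCall(protein_id, group, has_sp=False)

    charge = sum(
        (1 if aa in "KR" else -1 if aa in "DE" else 0) for aa in seq[1:6]
    )
    if charge < 1:
        return SignalPeptideCall(protein_id, group, has_sp=False)

    hydrophobic = False
    for s in range(2, min(25 - HYDROPATHY_WINDOW, len(seq) - HYDROPATHY_WINDOW) + 1):
        window = seq[s : s + HYDROPATHY_WINDOW]
        if sum(KYTE_DOOLITTLE[a] for a in window) / HYDROPATHY_WINDOW >= HYDROPATHY_MIN:
            hydrophobic = True
            break
    if not hydrophobic:
        return SignalPeptideCall(protein_id, group, has_sp=False)

    for p in range(MIN_CLEAVAGE, min(MAX_SP_REGION, len(seq) - 1) + 1):
        if seq[p - 3] in SMALL_NEUTRAL and seq[p - 1] in SMALL_NEUTRAL:
            return SignalPeptideCall(protein_id, group, has_sp=True, cleavage_position=p)
    return SignalPeptideCall(protein_id, group, has_sp=False)


@dataclass(frozen=True)
class GroupRatio:
    """With/without signal-peptide counts for one group.

    ``ratio`` is n_with / n_without (infinite when nobody lacks one);
    ``percent_with`` is 100 · n_with / n.  ``ratio_2dp`` rounds for
    presentation; full precision is retained internally.
    """

    group: str
    n_with: int
    n_without: int

    @property
    def n(self) -> int:
        return self.n_with + self.n_without

    @property
    def ratio(self) -> float:
        if self.n_without == 0:
            warnings.warn(f"group {self.group!r}: no proteins without a signal peptide")
            return math.inf
        return self.n_with / self.n_without

    @property
    def percent_with(self) -> float:
        return 100.0 * self.n_with / self.n

    @property
    def ratio_2dp(self) -> float:
        return round(self.ratio, 2)

    @classmethod
    def from_calls(cls, group: str, calls: Iterable[SignalPeptideCall]) -> "GroupRatio":
        calls = list(calls)
        if not calls:
            raise MgsConfigError(f"group {group!r} has no signal-peptide calls")
        n_with = sum(1 for c in calls if c.has_sp)
        return cls(group=group, n_with=n_with, n_without=len(calls) - n_with)

    @classmethod
    def from_percent(
        cls, group: str, percent_with: float, n_total: int | None = None
    ) -> "GroupRatio":
        """Reconstruct a ratio from a printed percentage.

        With ``n_total`` the counts are recovered as rounded integers (the
        way a published percentage arises from real counts); without it a
        nominal denominator of 1000 is used, which preserves the
        percentage but not count-rounding effects.
        """
        if not 0 <= percent_with <= 100:
            raise MgsConfigError("percent_with must be in [0, 100]")
        n = n_total if n_total is not None else 1000
        n_with = round(n * percent_with / 100.0)
        return cls(group=group, n_with=n_with, n_without=n - n_with)


def group_ratio(group: str, calls: Iterable[SignalPeptideCall]) -> GroupRatio:
    """Counts and with/without ratio for one group of calls."""
    return GroupRatio.from_calls(group, calls)


@dataclass(frozen=True)
class ProportionTest:
    statistic: float
    pvalue: float
    method: str
    note: str | None = None


def compare_sp_proportions(group_a: GroupRatio, group_b: GroupRatio) -> ProportionTest:
    """Two-sided test of equal signal-peptide proportions between groups.

    Chi-square with continuity correction on the 2×2 table; Fisher's exact
    test when any expected cell count is below 5 or a margin is zero.
    """
    if group_a.n == 0 or group_b.n == 0:
        raise MgsConfigError("both groups must be non-empty")
    table = [[group_a.n_with, group_a.n_without], [group_b.n_with, group_b.n_without]]
    row_sums = [sum(r) for r in table]
    col_sums = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in row_sums or 0 in col_sums:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return ProportionTest(odds, p, "fisher", note="degenerate table (zero margin)")
    res = stats.chi2_contingency(table, correction=True)
    if res.expected_freq.min() < 5:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return ProportionTest(odds, p, "fisher", note="expected cell count < 5")
    return ProportionTest(float(res.statistic), float(res.pvalue), "chi2_cc")


def read_calls_tsv(path: str | Path, group: str = "") -> list[SignalPeptideCall]:
    """Ingest external predictor output: protein id, Y/N, optional cleavage."""
    calls: list[SignalPeptideCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("protein"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise MgsDataError(f"{path}:{lineno}: expected >=2 columns")
            has_sp = fields[1].strip().upper() in ("Y", "YES", "1", "TRUE")
            cleav = (
                int(fields[2]) if has_sp and len(fields) > 2 and fields[2].strip() else None
            )
            calls.append(SignalPeptideCall(fields[0], group, has_sp, cleav))
    return calls


def write_ratio_tsv(ratios: Sequence[GroupRatio], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tn_with\tn_without\tpercent_with\tratio\n")
        for r in ratios:
            ratio = "inf" if r.n_without == 0 else f"{r.ratio_2dp:.2f}"
            fh.write(f"{r.group}\t{r.n_with}\t{r.n_without}\t{r.percent_with:.1f}\t{ratio}\n")
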