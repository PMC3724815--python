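"""miRanda-style local duplex alignment between a miRNA and a candidate target.

The miRNA (5'->3') is aligned against the reversed target so that the two
strands run antiparallel, as in a physical RNA:RNA hybrid.  Scoring follows
the miRanda matrix: +5 for G:C, +5 for A:U, +2 for the non-canonical G:U
wobble and -3 for every other residue pairing, with affine gap penalties.
Candidate sites must additionally pass four empirical binding-site rules
(seed-anchored mismatch constraints) and a duplex free-energy threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .seqs import RNASequence

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


class PairCategory(Enum):
    """Pairing category of one alignment column."""

    GC_MATCH = "GC"
    AU_MATCH = "AU"
    GU_WOBBLE = "GU"
    MISMATCH = "MM"
    GAP = "GAP"


def classify_column(mirna_char: str, target_char: str) -> PairCategory:
    """Categorize one alignment column from its two residues ('-' for a gap).

    G:U wobble covers both (G,U) and (U,G).  A column gapped in both rows is
    meaningless and rejected.
    """
    if mirna_char == "-" and target_char == "-":
        raise ValueError("alignment column gapped in both rows")
    if mirna_char == "-" or target_char == "-":
        return PairCategory.GAP
    pair = frozenset((mirna_char, target_char))
    if pair == frozenset("GC"):
        return PairCategory.GC_MATCH
    if pair == frozenset("AU"):
        return PairCategory.AU_MATCH
    if pair == frozenset("GU"):
        return PairCategory.GU_WOBBLE
    return PairCategory.MISMATCH


def infer_categories(mirna_row: str, target_row: str) -> list[PairCategory]:
    if len(mirna_row) != len(target_row):
        raise ValueError(
            f"aligned rows differ in length: {len(mirna_row)} vs {len(target_row)}"
        )
    return [classify_column(a, b) for a, b in zip(mirna_row, target_row)]


@dataclass(frozen=True)
class AlignConfig:
    """Scoring matrix, gap model and acceptance thresholds.

    The match/wobble/mismatch scores are the miRanda values.  Gap penalties
    are affine: a run of g gaps in one row costs gap_open + gap_extend*(g-1).
    Thresholds are deliberately permissive by default: a minimal
    rule-passing site (14 well-paired columns with the allowed mismatches)
    scores in the low 30s, so score_threshold=30 keeps essentially every
    candidate that satisfies the empirical rules and leaves refinement to
    the downstream classifier.  Stricter, miRanda-like values can be set in
    the config.
    """

    match_gc: float = 5.0
    match_au: float = 5.0
    wobble_gu: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    score_threshold: float = 30.0
    energy_threshold: float = -5.0  # kcal/mol, duplex MFE must be <= this
    max_sites: int = 16

    def pair_score(self, a: str, b: str) -> float:
        cat = classify_column(a, b)
        return {
            PairCategory.GC_MATCH: self.match_gc,
            PairCategory.AU_MATCH: self.match_au,
            PairCategory.GU_WOBBLE: self.wobble_gu,
            PairCategory.MISMATCH: self.mismatch,
        }[cat]


@dataclass
class DuplexAlignment:
    """One gapped local alignment between a miRNA and a target site.

    ``mirna_row`` runs 5'->3'; ``target_row`` is the target site as displayed
    in the duplex, i.e. 3'->5'.  ``target_start``/``target_end`` are 1-based
    inclusive coordinates on the ungapped target in its native 5'->3'
    orientation.
    """

    mirna_row: str
    target_row: str
    score: float
    target_start: int
    target_end: int
    mirna_id: str = ""
    target_id: str = ""
    categories: list[PairCategory] = field(default_factory=list)
    mfe: Optional[float] = None  # kcal/mol; filled in by the thermo module

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = infer_categories(self.mirna_row, self.target_row)
        if not (
            len(self.mirna_row) == len(self.target_row) == len(self.categories)
        ):
            raise ValueError("row/category lengths inconsistent")
        n_target_res = sum(1 for c in self.target_row if c != "-")
        if self.target_end - self.target_start + 1 != n_target_res:
            raise ValueError(
                "target coordinates span does not match ungapped target row"
            )

    @property
    def length(self) -> int:
        return len(self.categories)

    def ungapped_mirna(self) -> str:
        return self.mirna_row.replace("-", "")

    def ungapped_target(self) -> str:
        return self.target_row.replace("-", "")

    def subalignment(self, start: int, end: int) -> "DuplexAlignment":
        """Column slice [start, end], 1-based inclusive; coordinates adjusted."""
        if not 1 <= start <= end <= self.length:
            raise ValueError(f"invalid column window {start}..{end}")
        t_before = sum(1 for c in self.target_row[: start - 1] if c != "-")
        t_inside = sum(1 for c in self.target_row[start - 1 : end] if c != "-")
        # target_row is 3'->5': leading columns sit at the *end* coordinate
        new_end = self.target_end - t_before
        new_start = new_end - t_inside + 1
        return DuplexAlignment(
            mirna_row=self.mirna_row[start - 1 : end],
            target_row=self.target_row[start - 1 : end],
            score=float("nan"),
            target_start=new_start,
            target_end=new_end,
            mirna_id=self.mirna_id,
            target_id=self.target_id,
        )


def score_alignment(alignment: DuplexAlignment, cfg: AlignConfig) -> float:
    """Recompute the alignment score from its columns under ``cfg``.

    Gap runs are charged per row: each maximal run of gaps in one row costs
    gap_open + gap_extend*(len-1).
    """
    total = 0.0
    per_cat = {
        PairCategory.GC_MATCH: cfg.match_gc,
        PairCategory.AU_MATCH: cfg.match_au,
        PairCategory.GU_WOBBLE: cfg.wobble_gu,
        PairCategory.MISMATCH: cfg.mismatch,
    }
    for cat in alignment.categories:
        if cat is not PairCategory.GAP:
            total += per_cat[cat]
    for row in (alignment.mirna_row, alignment.target_row):
        run = 0
        for ch in row:
            if ch == "-":
                run += 1
            else:
                if run:
                    total += cfg.gap_open + cfg.gap_extend * (run - 1)
                run = 0
        if run:
            total += cfg.gap_open + cfg.gap_extend * (run - 1)
    return total


# ---------------------------------------------------------------------------
# Empirical binding-site rules
# ---------------------------------------------------------------------------

RULE_TOO_SHORT = "too_short"
RULE_I = "i_seed_anchor"        # no mismatches at columns 2-4
RULE_II = "ii_core_mismatches"  # fewer than 5 mismatches in columns 3-12
RULE_III = "iii_central_bulge"  # at least one mismatch in columns 9..L-5
RULE_IV = "iv_tail_mismatches"  # fewer than 2 mismatches in last 5 columns

MIN_RULE_LENGTH = 14


def check_empirical_rules(
    alignment: DuplexAlignment,
) -> tuple[bool, list[str]]:
    """Apply the four empirical site-identification rules.

    Columns are counted 1-based from the miRNA 5' end.  For rule purposes a
    "mismatch" is a MISMATCH or GAP column; a G:U wobble counts as pairing
    (it is positively scored and displayed as a pair).
    """
    L = alignment.length
    if L < MIN_RULE_LENGTH:
        return False, [RULE_TOO_SHORT]

    def is_mm(col: int) -> bool:  # 1-based
        return alignment.categories[col - 1] in (
            PairCategory.MISMATCH,
            PairCategory.GAP,
        )

    violated: list[str] = []
    if any(is_mm(c) for c in range(2, 5)):
        violated.append(RULE_I)
    if sum(is_mm(c) for c in range(3, 13)) >= 5:
        violated.append(RULE_II)
    if not any(is_mm(c) for c in range(9, L - 4)):
        violated.append(RULE_III)
    if sum(is_mm(c) for c in range(L - 4, L + 1)) >= 2:
        violated.append(RULE_IV)
    return not violated, violated


# ---------------------------------------------------------------------------
# Local alignment (Gotoh affine-gap dynamic programming)
# ---------------------------------------------------------------------------

_M, _IX, _IY, _START = 0, 1, 2, 3

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _score_matrix(cfg: AlignConfig) -> list[list[float]]:
    per_cat = {
        PairCategory.GC_MATCH: cfg.match_gc,
        PairCategory.AU_MATCH: cfg.match_au,
        PairCategory.GU_WOBBLE: cfg.wobble_gu,
        PairCategory.MISMATCH: cfg.mismatch,
    }
    bases = "ACGU"
    return [
        [per_cat[classify_column(a, b)] for b in bases] for a in bases
    ]


def _gotoh_local(
    mirna: str,
    rtarget: str,
    cfg: AlignConfig,
    masked: frozenset[int],
) -> tuple[float, Optional[tuple[str, str, int, int]]]:
    """Best local alignment of ``mirna`` against ``rtarget``.

    ``masked`` holds 0-based rtarget indices that may not be consumed (used
    to find multiple non-overlapping sites).  Returns (score, (mirna_row,
    target_row, j_start, j_end)) with 1-based inclusive rtarget coordinates,
    or (0, None) if no column pairs at a positive score.

    State Ix places a gap in the target row, Iy in the miRNA row; switching
    rows re-opens a run, so each per-row run costs gap_open+gap_extend*(g-1).
    Local alignments start and end in the pairing state M.
    """
    m, n = len(mirna), len(rtarget)
    go, ge = cfg.gap_open, cfg.gap_extend
    smat = _score_matrix(cfg)
    mcode = [_CODE[c] for c in mirna]
    tcode = [_CODE[c] for c in rtarget]
    open_col = [j == 0 or (j - 1) in masked for j in range(n + 1)]

    M = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    ptr_m = [[_START] * (n + 1) for _ in range(m + 1)]
    ptr_ix = [[_START] * (n + 1) for _ in range(m + 1)]
    ptr_iy = [[_START] * (n + 1) for _ in range(m + 1)]

    best, best_ij = 0.0, None
    for i in range(1, m + 1):
        srow = smat[mcode[i - 1]]
        m_up, ix_up, iy_up = M[i - 1], Ix[i - 1], Iy[i - 1]
        m_cur, ix_cur, iy_cur = M[i], Ix[i], Iy[i]
        pm, pix, piy = ptr_m[i], ptr_ix[i], ptr_iy[i]
        for j in range(0, n + 1):
            # Ix: gap in target row, consumes mirna[i-1] but no target
            # residue, so masked columns do not constrain it
            a_, b_, c_ = m_up[j] + go, ix_up[j] + ge, iy_up[j] + go
            if a_ >= b_ and a_ >= c_:
                ix_cur[j], pix[j] = a_, _M
            elif b_ >= c_:
                ix_cur[j], pix[j] = b_, _IX
            else:
                ix_cur[j], pix[j] = c_, _IY
            if open_col[j]:
                continue  # columns consuming this target residue forbidden
            # M: pair mirna[i-1] with rtarget[j-1]
            md, ixd, iyd = m_up[j - 1], ix_up[j - 1], iy_up[j - 1]
            prev, ptr = 0.0, _START
            if md > prev:
                prev, ptr = md, _M
            if ixd > prev:
                prev, ptr = ixd, _IX
            if iyd > prev:
                prev, ptr = iyd, _IY
            val = prev + srow[tcode[j - 1]]
            m_cur[j], pm[j] = val, ptr
            if val > best:
                best, best_ij = val, (i, j)
            # Iy: gap in miRNA row, consumes rtarget[j-1]
            a_, b_, c_ = m_cur[j - 1] + go, iy_cur[j - 1] + ge, ix_cur[j - 1] + go
            if a_ >= b_ and a_ >= c_:
                iy_cur[j], piy[j] = a_, _M
            elif b_ >= c_:
                iy_cur[j], piy[j] = b_, _IY
            else:
                iy_cur[j], piy[j] = c_, _IX

    if best_ij is None:
        return 0.0, None

    # traceback from the best pairing cell
    i, j = best_ij
    state = _M
    mrow: list[str] = []
    trow: list[str] = []
    j_end = j
    while True:
        if state == _M:
            mrow.append(mirna[i - 1])
            trow.append(rtarget[j - 1])
            nxt = ptr_m[i][j]
            i, j = i - 1, j - 1
            if nxt == _START:
                break
            state = nxt
        elif state == _IX:
            mrow.append(mirna[i - 1])
            trow.append("-")
            nxt = ptr_ix[i][j]
            i = i - 1
            state = nxt
        else:  # _IY
            mrow.append("-")
            trow.append(rtarget[j - 1])
            nxt = ptr_iy[i][j]
            j = j - 1
            state = nxt
    j_start = j + 1
    return best, ("".join(reversed(mrow)), "".join(reversed(trow)), j_start, j_end)


def _rescue_by_trimming(
    aln: DuplexAlignment, cfg: AlignConfig
) -> Optional[DuplexAlignment]:
    """Best-scoring sub-window of a rule-failing alignment that passes.

    The score-optimal local window often violates a site rule only at its
    edges (e.g. a seed-window mismatch, or two mismatches in the last five
    columns); a slightly trimmed window is still a valid local alignment and
    may satisfy the rules.  All sub-windows of length >= 14 whose boundary
    columns pair are tested; rejecting the whole region instead would
    discard legitimate sites.
    """
    L = aln.length
    best: Optional[DuplexAlignment] = None
    for start in range(1, L - MIN_RULE_LENGTH + 2):
        if aln.categories[start - 1] is PairCategory.GAP:
            continue
        for end in range(start + MIN_RULE_LENGTH - 1, L + 1):
            if end - start + 1 == L:
                continue  # the untrimmed window already failed
            if aln.categories[end - 1] is PairCategory.GAP:
                continue
            sub = aln.subalignment(start, end)
            sub.score = score_alignment(sub, cfg)
            if sub.score < cfg.score_threshold:
                continue
            if best is not None and sub.score <= best.score:
                continue
            if check_empirical_rules(sub)[0]:
                best = sub
    return best


def align_duplex(
    mirna: RNASequence,
    target: RNASequence,
    cfg: AlignConfig | None = None,
    energy_model=None,
) -> list[DuplexAlignment]:
    """Find accepted binding-site alignments of ``mirna`` on ``target``.

    The miRNA is aligned against the reversed target (antiparallel
    hybridization).  A candidate site is accepted when it (a) scores at or
    above ``cfg.score_threshold``, (b) passes the four empirical rules and
    (c) has duplex MFE at or below ``cfg.energy_threshold``.  Multiple
    non-overlapping sites are found greedily by descending score; every
    candidate above the score threshold masks its target span whether or not
    it is accepted, so weaker alternative sites can surface.
    """
    from .thermo import EnergyModel, duplex_mfe  # local import: avoid cycle

    cfg = cfg or AlignConfig()
    if energy_model is None:
        energy_model = EnergyModel()
    if not mirna.residues or not target.residues:
        raise ValueError("empty sequence")

    rtarget = target.residues[::-1]
    n = len(rtarget)
    masked: set[int] = set()
    accepted: list[DuplexAlignment] = []

    for _ in range(cfg.max_sites):
        score, hit = _gotoh_local(mirna.residues, rtarget, cfg, frozenset(masked))
        if hit is None or score < cfg.score_threshold:
            break
        mrow, trow, j_start, j_end = hit
        masked.update(range(j_start - 1, j_end))
        aln = DuplexAlignment(
            mirna_row=mrow,
            target_row=trow,
            score=score,
            target_start=n - j_end + 1,
            target_end=n - j_start + 1,
            mirna_id=mirna.identifier,
            target_id=target.identifier,
        )
        ok, violated = check_empirical_rules(aln)
        if not ok:
            rescued = _rescue_by_trimming(aln, cfg)
            if rescued is None:
                logger.debug(
                    "site %s:%d-%d rejected by rules %s",
                    target.identifier, aln.target_start, aln.target_end, violated,
                )
                continue
            aln = rescued
            aln.mirna_id = mirna.identifier
            aln.target_id = target.identifier
        aln.mfe = duplex_mfe(aln, energy_model)
        if aln.mfe > cfg.energy_threshold:
            logger.debug(
                "site %s:%d-%d rejected by energy %.2f > %.2f",
                target.identifier, aln.target_start, aln.target_end,
                aln.mfe, cfg.energy_threshold,
            )
            continue
        accepted.append(aln)

    accepted.sort(key=lambda a: -a.score)
    return accepted
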