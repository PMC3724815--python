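"""Labeled synthetic miRNA/target pairs with planted binding sites.

Each target carries one embedded site built from the reverse complement of
its miRNA and then degraded column-wise: seed columns (miRNA positions 2-8)
pair Watson-Crick with high probability in positives and low probability in
negatives, the 3' out-seed region with intermediate probabilities, and a
small fraction of planted pairs is flipped to a G:U wobble.  One central
non-pairing column is always planted (perfectly complementary duplexes are
not biological and are rejected by the central-bulge site rule).  Flanking
sequence is i.i.d. with configurable GC content.

The generator emulates seed-driven animal-style target recognition; it does
not model UTR context, site accessibility, conservation or expression-based
negative selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .duplex import AlignConfig, align_duplex
from .features import LABEL_NON_TARGET, LABEL_TARGET, FeatureTable, extract_features
from .seqs import RNASequence, Role
from .thermo import EnergyModel

logger = logging.getLogger(__name__)

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Pairing probabilities are per-column; ``wobble_rate`` is the chance a
    planted pair is G:U instead of Watson-Crick (where chemically possible).
    """

    n_pos: int = 200
    n_neg: int = 200
    mirna_length: int = 22
    target_length: int = 500
    seed_complementarity_pos: float = 0.95
    seed_complementarity_neg: float = 0.4
    out_seed_pairing_pos: float = 0.6
    out_seed_pairing_neg: float = 0.3
    wobble_rate: float = 0.08
    gc_content: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.seed_complementarity_pos,
            self.seed_complementarity_neg,
            self.out_seed_pairing_pos,
            self.out_seed_pairing_neg,
            self.wobble_rate,
            self.gc_content,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_pos, self.n_neg) < 0:
            raise ValueError("pair counts must be >= 0")
        if self.target_length < self.mirna_length + 10:
            raise ValueError(
                "target_length must be at least mirna_length + 10 "
                "(site plus minimal flanks)"
            )


def _random_residues(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=probs))


def _mismatch_partner(rng: np.random.Generator, mirna_char: str) -> str:
    banned = {_WC[mirna_char], _WOBBLE.get(mirna_char, "")}
    options = [r for r in "ACGU" if r not in banned]
    return str(rng.choice(options))


def _plant_site(
    rng: np.random.Generator, mirna: str, cfg: SyntheticConfig, positive: bool
) -> str:
    """Binding site 5'->3' on the target for this miRNA, degraded per class."""
    L = len(mirna)
    seed_p = cfg.seed_complementarity_pos if positive else cfg.seed_complementarity_neg
    out_p = cfg.out_seed_pairing_pos if positive else cfg.out_seed_pairing_neg
    # one guaranteed central non-pairing column (miRNA positions 10..L-6)
    forced_mm = int(rng.integers(10, L - 5))
    partners = []
    for k in range(1, L + 1):  # miRNA position, 5'->3'
        m = mirna[k - 1]
        if k == forced_mm:
            partners.append(_mismatch_partner(rng, m))
            continue
        p_pair = seed_p if 2 <= k <= 8 else out_p
        if rng.random() < p_pair:
            if m in _WOBBLE and rng.random() < cfg.wobble_rate:
                partners.append(_WOBBLE[m])
            else:
                partners.append(_WC[m])
        else:
            partners.append(_mismatch_partner(rng, m))
    # partner of miRNA position k sits at site position L-k+1 (antiparallel)
    return "".join(reversed(partners))


@dataclass(frozen=True)
class SyntheticPair:
    """One labeled miRNA/target pair with its planted-site coordinates."""

    mirna: RNASequence
    target: RNASequence
    label: str
    site_start: int  # 1-based inclusive on the target, 5'->3'
    site_end: int

    def __iter__(self):  # unpack as (mirna, target, label)
        return iter((self.mirna, self.target, self.label))


def generate_pairs(cfg: SyntheticConfig | None = None) -> list[SyntheticPair]:
    """Deterministic labeled pairs, each with one planted binding site."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    out = []
    specs = [(LABEL_TARGET, i, True) for i in range(cfg.n_pos)] + [
        (LABEL_NON_TARGET, i, False) for i in range(cfg.n_neg)
    ]
    for label, i, positive in specs:
        tag = "pos" if positive else "neg"
        mirna = _random_residues(rng, cfg.mirna_length, cfg.gc_content)
        site = _plant_site(rng, mirna, cfg, positive)
        start = int(rng.integers(0, cfg.target_length - len(site) + 1))
        flank_n = cfg.target_length - len(site)
        flanks = _random_residues(rng, flank_n, cfg.gc_content)
        target = flanks[:start] + site + flanks[start:]
        out.append(
            SyntheticPair(
                mirna=RNASequence(f"mir_{tag}_{i:04d}", mirna, Role.MIRNA),
                target=RNASequence(f"tgt_{tag}_{i:04d}", target, Role.TARGET),
                label=label,
                site_start=start + 1,
                site_end=start + len(site),
            )
        )
    return out


def generate_feature_table(
    cfg: SyntheticConfig | None = None,
    align_cfg: Optional[AlignConfig] = None,
    energy_model: Optional[EnergyModel] = None,
) -> FeatureTable:
    """Simulate pairs, align them, and extract features at the planted sites.

    The class label describes the planted site, so each pair contributes one
    row: the best-scoring accepted alignment that overlaps the planted-site
    interval.  Accepted chance alignments elsewhere on the target are
    ignored — attaching the pair label to them would mislabel both classes.
    Pairs whose planted site yields no accepted alignment are dropped and
    logged.
    """
    cfg = cfg or SyntheticConfig()
    align_cfg = align_cfg or AlignConfig()
    energy_model = energy_model or EnergyModel()
    ids, vectors, labels = [], [], []
    dropped = 0
    for pair in generate_pairs(cfg):
        mirna, target, label = pair
        sites = align_duplex(mirna, target, align_cfg, energy_model)
        planted = [
            a
            for a in sites
            if a.target_start <= pair.site_end and a.target_end >= pair.site_start
        ]
        if not planted:
            dropped += 1
            continue
        ids.append(f"{mirna.identifier}|{target.identifier}")
        vectors.append(extract_features(planted[0], energy_model))
        labels.append(label)
    if dropped:
        logger.info(
            "%d/%d pairs yielded no accepted alignment and were dropped",
            dropped, cfg.n_pos + cfg.n_neg,
        )
    if not ids:
        raise ValueError(
            "no pair produced an accepted alignment; relax the score/energy "
            "thresholds or raise the pairing probabilities"
        )
    return FeatureTable.from_rows(ids, vectors, labels)
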