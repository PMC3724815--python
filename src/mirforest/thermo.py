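"""Duplex free-energy (ΔG, kcal/mol) of miRNA:target hybrids at 37 °C.

Two backends are provided.  BUILTIN_NN is a self-contained nearest-neighbor
stacking model (Turner-style ΔG37 stack terms for Watson-Crick and G:U
steps, shipped as a versioned JSON table): the energy of an alignment is the
best (lowest) value over contiguous column windows of

    initiation + Σ stack terms over adjacent paired columns
               + internal penalty × unpaired columns in the window,

floored at 0 — a duplex that cannot reach a favourable energy contributes no
stability.  Picking the best window mirrors how a duplex folding engine only
pairs the favourable core of a site.  BUILTIN_NN is a consistent relative
stability score, not a calibrated absolute free energy.

EXTERNAL_DUPLEX delegates to an RNAduplex-compatible command-line engine on
the gap-stripped subsequences of the alignment.
"""

from __future__ import annotations

import json
import shutil
import subprocess
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources

from .duplex import DuplexAlignment, PairCategory

PAIRED = (PairCategory.GC_MATCH, PairCategory.AU_MATCH, PairCategory.GU_WOBBLE)


class Backend(Enum):
    BUILTIN_NN = "builtin"
    EXTERNAL_DUPLEX = "external"


@lru_cache(maxsize=1)
def _load_params() -> dict:
    with resources.files("mirforest.data").joinpath("nn_stacks.json").open() as fh:
        params = json.load(fh)
    # a stack read 5'AB3'/3'XY5' is the same duplex as 5'YX3'/3'BA5'
    stacks = dict(params["stacks"])
    for key, dg in list(stacks.items()):
        ab, xy = key.split("/")
        sym = f"{xy[::-1]}/{ab[::-1]}"
        stacks.setdefault(sym, dg)
    params["stacks"] = stacks
    return params


@dataclass(frozen=True)
class EnergyModel:
    """Energy backend selection plus nearest-neighbor parameters."""

    backend: Backend = Backend.BUILTIN_NN
    external_command: str = "RNAduplex"
    params: dict = field(default_factory=_load_params)

    @property
    def stacks(self) -> dict:
        return self.params["stacks"]


def _stack_term(model: EnergyModel, a1: str, t1: str, a2: str, t2: str) -> float:
    key = f"{a1}{a2}/{t1}{t2}"
    try:
        return model.stacks[key]
    except KeyError:
        return model.params["wobble_default"]


def _builtin_mfe(alignment: DuplexAlignment, model: EnergyModel) -> float:
    cats = alignment.categories
    L = len(cats)
    paired = [c in PAIRED for c in cats]
    if not any(paired):
        return 0.0  # no duplex
    init = model.params["duplex_initiation"]
    loop = model.params["internal_penalty"]
    mrow, trow = alignment.mirna_row, alignment.target_row
    best = 0.0
    for a in range(L):
        dg = init
        for b in range(a, L):
            if b > a:
                if paired[b] and paired[b - 1]:
                    dg += _stack_term(
                        model, mrow[b - 1], trow[b - 1], mrow[b], trow[b]
                    )
                elif not paired[b]:
                    dg += loop
            elif not paired[b]:
                dg += loop
            if dg < best:
                best = dg
    return best


def _external_mfe(alignment: DuplexAlignment, model: EnergyModel) -> float:
    exe = shutil.which(model.external_command)
    if exe is None:
        raise RuntimeError(
            f"external duplex engine {model.external_command!r} not found on PATH"
        )
    mirna = alignment.ungapped_mirna()            # 5'->3'
    site = alignment.ungapped_target()[::-1]      # displayed 3'->5' -> native
    if not mirna or not site:
        return 0.0
    out = subprocess.run(
        [exe], input=f"{mirna}\n{site}\n", capture_output=True, text=True,
        check=True,
    ).stdout
    # last parenthesised number on the hit line is the energy
    line = out.strip().splitlines()[-1]
    return float(line.rsplit("(", 1)[1].rstrip(")").strip())


def duplex_mfe(alignment: DuplexAlignment, model: EnergyModel | None = None) -> float:
    """ΔG (kcal/mol) of the full alignment; 0.0 when nothing pairs."""
    model = model or EnergyModel()
    if alignment.length < 2:
        raise ValueError("alignment must have at least 2 columns")
    if model.backend is Backend.BUILTIN_NN:
        return _builtin_mfe(alignment, model)
    return _external_mfe(alignment, model)


def seed_mfe(alignment: DuplexAlignment, model: EnergyModel | None = None) -> float:
    """ΔG of the seed sub-duplex: alignment columns 2-8, gap columns dropped.

    Energy is a property of the hybridizing sequences, so gaps are stripped
    from the seed window before evaluation.
    """
    model = model or EnergyModel()
    if alignment.length < 8:
        raise ValueError("alignment too short for a seed window (needs >= 8 columns)")
    sub = alignment.subalignment(2, 8)
    cols = [
        (m, t)
        for m, t, c in zip(sub.mirna_row, sub.target_row, sub.categories)
        if c is not PairCategory.GAP
    ]
    if not cols:
        return 0.0
    n_t = sum(1 for _, t in cols if t != "-")
    stripped = DuplexAlignment(
        mirna_row="".join(m for m, _ in cols),
        target_row="".join(t for _, t in cols),
        score=float("nan"),
        target_start=1,
        target_end=n_t,
    )
    if stripped.length < 2:
        return 0.0
    return duplex_mfe(stripped, model)
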