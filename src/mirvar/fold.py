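"""Hairpin secondary-structure stability change between alleles.

The built-in folder is a base-pair-maximisation dynamic programme (the
classic quadratic-table recursion) over non-crossing structures with a
minimum hairpin-loop length: each pair scores -1, so a more negative score
means a more paired — read: more stable — structure. It is not a
nearest-neighbour thermodynamic model; free-energy engines (e.g. RNAfold)
can be attached through the engine plug-in contract, which takes a callable
``seq -> FoldResult`` and records the engine name in the result, so scores
from different engines are never silently mixed.

Allowed pairs are Watson-Crick plus the G:U wobble (``allow_wobble=False``
restricts to strict Watson-Crick); N never pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from mirvar.alleles import apply_allele
from mirvar.io import normalise_rna

#: the window size within which variant effects on structure are predicted
MAX_FOLD_LENGTH = 2000

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = _WC_PAIRS | {("G", "U"), ("U", "G")}


def can_pair(x: str, y: str, *, allow_wobble: bool = True) -> bool:
    pairs = _WOBBLE_PAIRS if allow_wobble else _WC_PAIRS
    return (x, y) in pairs


@dataclass(frozen=True)
class FoldResult:
    """A sequence, its dot-bracket structure, and the folding score."""

    sequence: str
    structure: str
    score: float
    engine: str = "builtin"

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure and sequence lengths differ")

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        """Base pairs as 0-based (i, j) index pairs, i < j."""
        stack: list[int] = []
        out = set()
        for k, c in enumerate(self.structure):
            if c == "(":
                stack.append(k)
            elif c == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                out.add((stack.pop(), k))
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return frozenset(out)

    @property
    def paired_mask(self) -> tuple[bool, ...]:
        return tuple(c != "." for c in self.structure)


def fold_hairpin(
    seq: str,
    min_loop: int = 3,
    *,
    allow_wobble: bool = True,
) -> FoldResult:
    """Maximum-cardinality non-crossing pairing with a minimum loop length.

    A pair (i, j) requires at least ``min_loop`` unpaired bases between its
    ends. The traceback is deterministic: on ties, pairing the interval ends
    is preferred over leaving an end unpaired, which is preferred over
    bifurcation at the smallest split point — so the dot-bracket output is
    reproducible.
    """
    rna = normalise_rna(seq)
    n = len(rna)
    if n > MAX_FOLD_LENGTH:
        raise ValueError(f"sequence of {n} nt exceeds the {MAX_FOLD_LENGTH}-nt window")
    if n == 0:
        return FoldResult("", "", 0.0)

    def pairable(i: int, j: int) -> bool:
        return j - i > min_loop and can_pair(rna[i], rna[j], allow_wobble=allow_wobble)

    # table[i][j] = max pairs in rna[i..j]
    table = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = max(table[i + 1][j], table[i][j - 1])
            if pairable(i, j):
                inner = table[i + 1][j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + 1)
            for k in range(i + 1, j):
                cand = table[i][k] + table[k + 1][j]
                if cand > best:
                    best = cand
            table[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        score = table[i][j]
        if score == 0:
            continue
        inner = table[i + 1][j - 1] if i + 1 <= j - 1 else 0
        if pairable(i, j) and score == inner + 1:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
        elif score == table[i + 1][j]:
            stack.append((i + 1, j))
        elif score == table[i][j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if table[i][k] + table[k + 1][j] == score:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return FoldResult(rna, "".join(structure), -float(table[0][n - 1]))


FoldEngine = Callable[[str], FoldResult]


@dataclass(frozen=True)
class StabilityDelta:
    """Stability change between alleles: ``delta = score_alt - score_ref``.

    A negative delta flags stabilisation by the alternative allele.
    ``changed_positions`` lists the 1-based positions whose paired status
    differs between the two structures, for region-impact reporting.
    """

    score_ref: float
    score_alt: float
    delta: float
    fold_ref: FoldResult
    fold_alt: FoldResult
    engine: str

    @property
    def changed_positions(self) -> tuple[int, ...]:
        ref_mask = self.fold_ref.paired_mask
        alt_mask = self.fold_alt.paired_mask
        return tuple(
            k + 1 for k, (a, b) in enumerate(zip(ref_mask, alt_mask)) if a != b
        )


def stability_delta(
    ref_seq: str,
    snp_pos_1based: int,
    ref: str,
    alt: str,
    *,
    engine: str | FoldEngine = "builtin",
    on_reverse_strand: bool = False,
    min_loop: int = 3,
) -> StabilityDelta:
    """Fold both alleles of a hairpin and report the score change.

    ``engine`` is either ``"builtin"`` (base-pair maximisation) or a
    callable implementing the plug-in contract; the engine name is recorded
    so scores from different models are never compared silently.
    """
    alt_seq = apply_allele(ref_seq, snp_pos_1based, ref, alt, on_reverse_strand)
    if engine == "builtin":
        fold = lambda s: fold_hairpin(s, min_loop=min_loop)
        engine_name = "builtin"
    elif callable(engine):
        fold = engine
        engine_name = getattr(engine, "__name__", "external")
    else:
        raise ValueError(f"unknown folding engine {engine!r}")
    fr = fold(normalise_rna(ref_seq))
    fa = fold(alt_seq)
    return StabilityDelta(
        score_ref=fr.score,
        score_alt=fa.score,
        delta=fa.score - fr.score,
        fold_ref=fr,
        fold_alt=fa,
        engine=engine_name,
    )
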