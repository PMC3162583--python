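"""miRanda-style duplex scoring and variant-induced target-site delta selection.

A mature miRNA (5'->3') is aligned antiparallel against a genomic window by
Smith-Waterman local alignment in which a "match" is a Watson-Crick pair
(A:U, G:C), G:U wobbles score an intermediate bonus, and per-position pair
scores are doubled inside the miRNA seed (positions 2-8), the region that
dominates target recognition.  Gaps are affine.  A per-pair free-energy
surrogate (G:C -2.0, A:U -1.0, G:U -0.5 kcal/mol) is accumulated over the
optimal trace; the duplex total defaults to the complementarity score alone
(energy weight lambda = 0).

For every variant, equal wild-type and mutant windows centred on the variant
are scored against every miRNA; the delta = wt_total - mut_total is positive
when the substitution destroys a site and negative when it creates one, and
the top fraction (default 5%) of deltas is flagged for follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoringParams",
    "DuplexScore",
    "VariantRecord",
    "DeltaScore",
    "build_windows",
    "duplex_score",
    "delta_scores",
    "select_top_fraction",
]

_RNA = set("ACGU")


def _to_rna(seq: str, what: str) -> str:
    s = str(seq).upper().replace("T", "U")
    bad = set(s) - _RNA
    if bad:
        raise ValueError(f"{what} contains non-ACGUT characters: {sorted(bad)}")
    return s


# pair classification on RNA alphabet
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScoringParams:
    """Alignment and energy-surrogate parameters (miRanda-like defaults)."""

    match_wc: float = 5.0
    wobble_gu: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2  # 1-based miRNA position, inclusive
    seed_end: int = 8
    seed_weight: float = 2.0
    energy_weights: dict = field(
        default_factory=lambda: {"GC": -2.0, "AU": -1.0, "GU": -0.5}
    )
    energy_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.seed_weight < 1:
            raise ValueError("seed_weight must be >= 1")

    def pair_score(self, mirna_base: str, target_base: str, mirna_pos: int) -> float:
        pair = (mirna_base, target_base)
        if pair in _WC:
            s = self.match_wc
        elif pair in _WOBBLE:
            s = self.wobble_gu
        else:
            s = self.mismatch
        if self.seed_start <= mirna_pos <= self.seed_end:
            s *= self.seed_weight
        return s

    def pair_energy(self, mirna_base: str, target_base: str) -> float:
        pair = (mirna_base, target_base)
        if pair in _WC:
            key = "GC" if "G" in pair else "AU"
            return self.energy_weights[key]
        if pair in _WOBBLE:
            return self.energy_weights["GU"]
        return 0.0


@dataclass(frozen=True)
class DuplexScore:
    complementarity: float
    energy: float
    total: float
    # aligned (mirna_pos, window_pos), both 1-based on the input orientations
    trace: tuple = ()

    @property
    def footprint(self) -> tuple[int, int] | None:
        """1-based window positions covered by the optimal alignment."""
        if not self.trace:
            return None
        cols = [w for _, w in self.trace]
        return min(cols), max(cols)


@dataclass(frozen=True)
class VariantRecord:
    seq_id: str
    pos: int  # 1-based
    ref: str
    alt: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("variant position is 1-based and must be >= 1")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide substitutions are supported")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"ref and alt are identical at {self.seq_id}:{self.pos}")


def build_windows(
    target_seq: str, variant: VariantRecord, flank: int = 25
) -> tuple[str, str, int]:
    """Wild-type and mutant windows of +/-``flank`` nt around the variant.

    Returns (wt_window, mut_window, window_start) with ``window_start`` the
    1-based position of the window's first base on the target; windows are
    clipped at the sequence ends and differ at exactly the variant position.
    """
    seq = str(target_seq).upper()
    pos = variant.pos
    if pos > len(seq):
        raise ValueError(f"position {pos} beyond {variant.seq_id} (len {len(seq)})")
    if seq[pos - 1] != variant.ref.upper():
        raise ValueError(
            f"reference mismatch at {variant.seq_id}:{pos}: "
            f"sequence has {seq[pos - 1]!r}, variant says {variant.ref!r}"
        )
    start = max(1, pos - flank)
    end = min(len(seq), pos + flank)
    wt = seq[start - 1 : end]
    offset = pos - start
    mut = wt[:offset] + variant.alt.upper() + wt[offset + 1 :]
    return wt, mut, start


def duplex_score(
    mirna: str, window: str, params: ScoringParams | None = None
) -> DuplexScore:
    """Optimal antiparallel local alignment of a miRNA against a window.

    The miRNA (5'->3') pairs with the window read 3'->5'; the dynamic
    program is Gotoh's affine-gap local alignment, with the first gapped
    position costing ``gap_open`` and each further one ``gap_extend``.
    Tie-breaking is deterministic: the optimum cell is the first reached in
    row-major order that strictly improves the score, and the traceback
    prefers pairing over a gap in the window over a gap in the miRNA.
    """
    if params is None:
        params = ScoringParams()
    m_seq = _to_rna(mirna, "miRNA")
    w_seq = _to_rna(window, "window")
    n, L = len(m_seq), len(w_seq)
    if n < 2 or L < 2:
        raise ValueError("sequences too short to align")
    w_rev = w_seq[::-1]
    neg = -1e18
    M = np.full((n + 1, L + 1), 0.0)
    Ix = np.full((n + 1, L + 1), neg)  # gap in window (miRNA base unpaired)
    Iy = np.full((n + 1, L + 1), neg)  # gap in miRNA (window base unpaired)
    M[0, :] = 0.0
    M[:, 0] = 0.0
    # M holds best local score ending at (i, j) with i paired to j (or 0 = empty)
    best = 0.0
    best_cell = None
    ptrM = np.zeros((n + 1, L + 1), dtype=np.int8)  # 0 start, 1 M, 2 Ix, 3 Iy
    ptrX = np.zeros((n + 1, L + 1), dtype=np.int8)  # 1 from M, 2 extend
    ptrY = np.zeros((n + 1, L + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, L + 1):
            s = params.pair_score(m_seq[i - 1], w_rev[j - 1], i)
            prev = 0.0
            src = 0
            if M[i - 1, j - 1] > prev:
                prev, src = M[i - 1, j - 1], 1
            if Ix[i - 1, j - 1] > prev:
                prev, src = Ix[i - 1, j - 1], 2
            if Iy[i - 1, j - 1] > prev:
                prev, src = Iy[i - 1, j - 1], 3
            M[i, j] = prev + s
            ptrM[i, j] = src
            ox = M[i - 1, j] + params.gap_open
            ex = Ix[i - 1, j] + params.gap_extend
            if ox >= ex:
                Ix[i, j], ptrX[i, j] = ox, 1
            else:
                Ix[i, j], ptrX[i, j] = ex, 2
            oy = M[i, j - 1] + params.gap_open
            ey = Iy[i, j - 1] + params.gap_extend
            if oy >= ey:
                Iy[i, j], ptrY[i, j] = oy, 1
            else:
                Iy[i, j], ptrY[i, j] = ey, 2
            if M[i, j] > best + 1e-12:
                best = M[i, j]
                best_cell = (i, j)
    if best_cell is None:
        return DuplexScore(complementarity=0.0, energy=0.0, total=0.0, trace=())
    # traceback through M/Ix/Iy states collecting paired positions
    trace = []
    state = 1
    i, j = best_cell
    while i > 0 and j > 0:
        if state == 1:
            trace.append((i, L - j + 1))  # window pos back in 5'->3' coordinates
            state = ptrM[i, j]
            i, j = i - 1, j - 1
            if state == 0:
                break
        elif state == 2:
            state = 1 if ptrX[i, j] == 1 else 2
            i -= 1
        else:
            state = 1 if ptrY[i, j] == 1 else 3
            j -= 1
    trace.reverse()
    energy = 0.0
    for mi, wj in trace:
        energy += params.pair_energy(m_seq[mi - 1], w_seq[wj - 1])
    total = best - params.energy_lambda * energy
    return DuplexScore(
        complementarity=float(best),
        energy=float(energy),
        total=float(total),
        trace=tuple(trace),
    )


def delta_scores(
    mirnas: dict[str, str],
    targets: dict[str, str],
    variants,
    params: ScoringParams | None = None,
    flank: int = 25,
) -> pd.DataFrame:
    """Score every (miRNA, variant) combination on wild-type and mutant windows.

    ``variants`` is an iterable of :class:`VariantRecord`; the result has one
    row per combination with delta = wt_total - mut_total, sorted descending.
    """
    if params is None:
        params = ScoringParams()
    rows = []
    for var in variants:
        if var.seq_id not in targets:
            raise KeyError(f"variant references unknown target {var.seq_id!r}")
        wt, mut, start = build_windows(targets[var.seq_id], var, flank)
        for mid, mseq in mirnas.items():
            wt_score = duplex_score(mseq, wt, params)
            mut_score = duplex_score(mseq, mut, params)
            rows.append(
                {
                    "mirna_id": mid,
                    "seq_id": var.seq_id,
                    "variant_label": var.label or f"{var.pos}{var.ref}>{var.alt}",
                    "pos": var.pos,
                    "window_start": start,
                    "wt_total": wt_score.total,
                    "mut_total": mut_score.total,
                    "delta": wt_score.total - mut_score.total,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values("delta", ascending=False, kind="stable").reset_index(
        drop=True
    )


def select_top_fraction(deltas: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Flag deltas at or above the empirical (1 - fraction) quantile.

    The threshold uses the linear-interpolation (type-7) quantile; ties at
    the cut are included.  The threshold is attached as frame metadata in
    ``attrs['threshold']``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(deltas) == 0:
        raise ValueError("no delta scores to select from")
    thr = float(np.quantile(deltas["delta"].to_numpy(), 1.0 - fraction))
    out = deltas.copy()
    out["selected"] = out["delta"] >= thr
    out.attrs["threshold"] = thr
    return out
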