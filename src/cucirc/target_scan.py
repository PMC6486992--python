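"""Plant miRNA target-site scoring and the circRNA-miRNA-mRNA edge table.

Sites are scored with the additive penalty scheme conventional for plant
miRNA target prediction: 1.0 per mismatch, 0.5 per G:U wobble, 2.0 per
gap position, with penalties doubled over miRNA positions 2-13 (the
seed-proximal region, counted from the miRNA 5' end); a perfect reverse
complement scores 0 and hits are kept up to a penalty cutoff (default 4.0).

circRNA sequences are scanned as the back-splice-joined molecule: the
spliced exon sequence for exonic circs (genomic span otherwise), with
miRNA_length - 1 leading bases wrapped past the junction so junction-
spanning sites are visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classify import OriginCall, GeneIndex
from .io_formats import CircRecord, GeneModel, fetch_sequence, reverse_complement

__all__ = [
    "TargetHit",
    "NetworkEdge",
    "score_site",
    "scan_target",
    "scan_many",
    "circ_sequence",
    "build_network",
]

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0
SEED_RANGE = (2, 13)  # inclusive, 1-based from miRNA 5' end; penalties doubled
DEFAULT_CUTOFF = 4.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def _encode(seq: str, what: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol {exc.args[0]!r} in {what}") from None


def _position_weights(length: int) -> np.ndarray:
    w = np.ones(length)
    lo, hi = SEED_RANGE
    w[lo - 1 : hi] = 2.0
    return w


# penalty of miRNA base m paired against base r of revcomp(window):
# identical -> complementary pairing (0); miRNA G vs target U and miRNA U vs
# target G are wobbles (0.5); anything else, including N, mismatches (1).
_PAIR_PENALTY = np.full((5, 5), MISMATCH)
for _b in range(4):
    _PAIR_PENALTY[_b, _b] = 0.0
_PAIR_PENALTY[_CODE["G"], _CODE["A"]] = WOBBLE  # G:U wobble
_PAIR_PENALTY[_CODE["T"], _CODE["C"]] = WOBBLE  # U:G wobble
_PAIR_PENALTY[_CODE["N"], :] = MISMATCH
_PAIR_PENALTY[:, _CODE["N"]] = MISMATCH


def _symbols(m: np.ndarray, r: np.ndarray) -> str:
    out = []
    for a, b in zip(m, r):
        pen = _PAIR_PENALTY[a, b]
        out.append("|" if pen == 0 else "o" if pen == WOBBLE else ".")
    return "".join(out)


def score_site(mirna_seq: str, target_window: str) -> Tuple[float, str]:
    """Penalty score and pairing string of a miRNA against one target window.

    The window length may differ from the miRNA by up to 4 nt; length
    differences are absorbed by gap positions (2.0 each, doubled in the
    seed-proximal region) through a global minimum-penalty alignment.
    """
    m = _encode(mirna_seq, "miRNA")
    w = _encode(target_window, "target window")
    if abs(len(w) - len(m)) > 4:
        raise ValueError("window length must be within +/-4 of the miRNA length")
    r = _COMPLEMENT_CODE[w][::-1]  # miRNA 5'->3' pairs target 3'->5'
    weights = _position_weights(len(m))

    if len(m) == len(r):
        gapless = float((_PAIR_PENALTY[m, r] * weights).sum())
    else:
        gapless = np.inf

    # global DP allowing gaps; gap cost keyed on the current miRNA position
    nm, nr = len(m), len(r)
    big = np.inf
    D = np.full((nm + 1, nr + 1), big)
    D[0, 0] = 0.0
    for i in range(1, nm + 1):
        D[i, 0] = D[i - 1, 0] + GAP * weights[i - 1]
    for j in range(1, nr + 1):
        D[0, j] = D[0, j - 1] + GAP * weights[0]
    for i in range(1, nm + 1):
        wi = weights[i - 1]
        for j in range(1, nr + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + _PAIR_PENALTY[m[i - 1], r[j - 1]] * wi,
                D[i - 1, j] + GAP * wi,
                D[i, j - 1] + GAP * wi,
            )
    score = float(min(D[nm, nr], gapless))
    sym = _symbols(m, r) if nm == nr else ""
    return score, sym


@dataclass
class TargetHit:
    query_mirna: str
    target_id: str
    target_start: int  # 1-based on the scanned target sequence
    target_end: int
    score: float
    alignment: str


def scan_target(
    mirna_seq: str,
    target_seq: str,
    cutoff: float = DEFAULT_CUTOFF,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> List[TargetHit]:
    """Slide the miRNA over all equal-length windows of the target.

    Windows are scored gap-free (a gap pair already costs at least the
    default cutoff, so gapped alignments cannot rescue an equal-length
    window); non-overlapping hits with score <= cutoff are reported,
    best-score first among overlapping candidates.
    """
    m = _encode(mirna_seq, "miRNA")
    if not (18 <= len(m) <= 24):
        raise ValueError(f"miRNA length must be 18-24 nt, got {len(m)}")
    t = _encode(target_seq, "target")
    L = len(m)
    if len(t) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    rc = _COMPLEMENT_CODE[windows][:, ::-1]
    weights = _position_weights(L)
    scores = (_PAIR_PENALTY[m[None, :], rc] * weights[None, :]).sum(axis=1)

    order = sorted(np.flatnonzero(scores <= cutoff), key=lambda s: (scores[s], s))
    taken: List[Tuple[int, int]] = []
    hits: List[TargetHit] = []
    for s in order:
        lo, hi = int(s), int(s) + L - 1
        if any(lo <= e and b <= hi for b, e in taken):
            continue
        taken.append((lo, hi))
        hits.append(
            TargetHit(
                query_mirna=mirna_id,
                target_id=target_id,
                target_start=lo + 1,
                target_end=hi + 1,
                score=float(scores[s]),
                alignment=_symbols(m, rc[s]),
            )
        )
    hits.sort(key=lambda h: h.target_start)
    return hits


def scan_many(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """All miRNA x target hits as one table."""
    rows = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            for h in scan_target(mirnas[mid], targets[tid], cutoff, mid, tid):
                rows.append(
                    {
                        "mirna": h.query_mirna,
                        "target_id": h.target_id,
                        "target_start": h.target_start,
                        "target_end": h.target_end,
                        "score": h.score,
                        "alignment": h.alignment,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["mirna", "target_id", "target_start", "target_end", "score", "alignment"],
    )


def circ_sequence(
    circ: CircRecord,
    genome: Mapping[str, str],
    gene: Optional[GeneModel] = None,
    wrap: int = 0,
) -> str:
    """Back-splice-joined sequence of a circRNA.

    Spliced exon sequence (genomic order, plus strand) when a parent gene is
    given and intersects the span; the plain genomic span otherwise.  ``wrap``
    appends that many leading bases at the end so windows can span the
    junction of the circular molecule.
    """
    if gene is not None:
        pieces = [
            fetch_sequence(genome, circ.chrom, max(s, circ.start), min(e, circ.end))
            for s, e in gene.exons_genomic
            if max(s, circ.start) <= min(e, circ.end)
        ]
        seq = "".join(pieces)
    else:
        seq = ""
    if not seq:
        seq = fetch_sequence(genome, circ.chrom, circ.start, circ.end)
    if wrap > 0:
        seq = seq + seq[: min(wrap, len(seq))]
    return seq


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    edge_type: str  # "circ-miRNA" | "miRNA-mRNA"


def build_network(
    circ_hits: pd.DataFrame,
    mrna_hits: pd.DataFrame,
    de_circs: Iterable[str],
) -> List[NetworkEdge]:
    """Assemble the regulatory edge table restricted to DE circRNAs.

    circ-miRNA edges keep hits whose circ is differentially expressed;
    miRNA-mRNA edges keep miRNAs retained on the circ side (a retained miRNA
    with no mRNA hits simply contributes no mRNA edges).
    """
    de = set(de_circs)
    edges: List[NetworkEdge] = []
    kept_mirnas: Set[str] = set()
    if len(circ_hits):
        pairs = {
            (row["target_id"], row["mirna"])
            for _, row in circ_hits.iterrows()
            if row["target_id"] in de
        }
        for circ, mirna in sorted(pairs):
            edges.append(NetworkEdge(circ, mirna, "circ-miRNA"))
            kept_mirnas.add(mirna)
    if len(mrna_hits):
        pairs = {
            (row["mirna"], row["target_id"])
            for _, row in mrna_hits.iterrows()
            if row["mirna"] in kept_mirnas
        }
        for mirna, mrna in sorted(pairs):
            edges.append(NetworkEdge(mirna, mrna, "miRNA-mRNA"))
    return edges
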