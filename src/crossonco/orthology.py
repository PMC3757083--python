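"""Fish-to-human ortholog assignment from similarity scores and synteny.

The primary signal is reciprocal best hits (RBH) in a cross-species
similarity table (a stand-in for protein similarity-search bit scores).
Because the teleost whole-genome duplication leaves up to two fish paralogs
per human gene, pure RBH misses the second paralog; ambiguous cases (exact
ties, or competing hits scoring within a ratio ``tie_ratio`` of a gene's
best hit) are arbitrated by conserved synteny: a candidate pair gains
support from every other assignment whose genes are within ``W`` ordinal
positions of it in both species.  The accepted table is a function
fish gene -> human gene; a human gene may appear more than once (paralogs).

Conserved synteny blocks are produced by greedy chaining of accepted pairs
along the human gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GeneRecord

__all__ = [
    "OrthologPair",
    "SyntenyBlock",
    "reciprocal_best_hits",
    "synteny_support",
    "refine_orthologs",
    "synteny_blocks",
    "block_size_histogram",
]


@dataclass(frozen=True)
class OrthologPair:
    human_gene_id: str
    fish_gene_id: str
    score: float
    rbh: bool
    ambiguous: bool = False
    synteny_support: int = 0
    accepted: bool = False


@dataclass
class SyntenyBlock:
    """A chained run of ortholog pairs co-localized in both species."""

    block_id: int
    human_chromosome: str
    fish_chromosome: str
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.pairs)


def reciprocal_best_hits(similarity: pd.DataFrame) -> list[OrthologPair]:
    """Candidate pairs where each gene attains the other's maximum score.

    Exact score ties produce multiple candidates, flagged ``ambiguous``.
    """
    if similarity.empty:
        return []
    best_h = similarity.groupby("human_gene_id")["score"].transform("max")
    best_f = similarity.groupby("fish_gene_id")["score"].transform("max")
    is_best_h = similarity["score"] == best_h
    is_best_f = similarity["score"] == best_f
    rbh = similarity[is_best_h & is_best_f]
    h_multi = rbh.groupby("human_gene_id")["fish_gene_id"].transform("size") > 1
    f_multi = rbh.groupby("fish_gene_id")["human_gene_id"].transform("size") > 1
    ambiguous = (h_multi | f_multi).to_numpy()
    return [
        OrthologPair(
            human_gene_id=r.human_gene_id,
            fish_gene_id=r.fish_gene_id,
            score=float(r.score),
            rbh=True,
            ambiguous=bool(amb),
        )
        for r, amb in zip(rbh.itertuples(index=False), ambiguous)
    ]


class _GeneIndex:
    def __init__(self, genes: Sequence[GeneRecord]):
        self.chrom = {g.gene_id: g.chromosome for g in genes}
        self.ordinal = {g.gene_id: g.ordinal for g in genes}

    def known(self, gene_id: str) -> bool:
        return gene_id in self.chrom


def synteny_support(
    human_gene_id: str,
    fish_gene_id: str,
    assignments: Sequence[tuple[str, str]],
    human_genes: Sequence[GeneRecord] | _GeneIndex,
    fish_genes: Sequence[GeneRecord] | _GeneIndex,
    window: int = 100,
) -> int:
    """Count assignments co-localized with (human, fish) in both species.

    An assignment (h', f') supports the pair iff h' is on the same human
    chromosome within ``window`` ordinal positions of h, and likewise f'
    for f.  The pair itself never counts.
    """
    hidx = human_genes if isinstance(human_genes, _GeneIndex) else _GeneIndex(human_genes)
    fidx = fish_genes if isinstance(fish_genes, _GeneIndex) else _GeneIndex(fish_genes)
    if not (hidx.known(human_gene_id) and fidx.known(fish_gene_id)):
        return 0
    hc, ho = hidx.chrom[human_gene_id], hidx.ordinal[human_gene_id]
    fc, fo = fidx.chrom[fish_gene_id], fidx.ordinal[fish_gene_id]
    count = 0
    for h2, f2 in assignments:
        if (h2, f2) == (human_gene_id, fish_gene_id):
            continue
        if not (hidx.known(h2) and fidx.known(f2)):
            continue
        if hidx.chrom[h2] != hc or fidx.chrom[f2] != fc:
            continue
        if abs(hidx.ordinal[h2] - ho) <= window and abs(fidx.ordinal[f2] - fo) <= window:
            count += 1
    return count


def refine_orthologs(
    similarity: pd.DataFrame,
    human_genes: Sequence[GeneRecord],
    fish_genes: Sequence[GeneRecord],
    window: int = 100,
    tie_ratio: float = 0.9,
) -> pd.DataFrame:
    """Build the accepted ortholog table from similarity scores and synteny.

    Procedure:

    1. each fish gene's *candidates* are its hits scoring within
       ``tie_ratio`` of its best hit;
    2. fish genes whose single candidate is an unambiguous RBH are accepted
       outright;
    3. remaining fish genes are arbitrated by synteny: support is counted
       against a context of accepted pairs plus every unresolved fish
       gene's provisional best hit (so that co-duplicated neighborhoods can
       support each other); the candidate maximizing (support, score,
       lexicographic id) wins and is accepted if it is an RBH or has
       positive support -- the latter admits second fish paralogs that are
       only one-way best hits to an already-claimed human gene.

    Returns a DataFrame with columns ``human_gene_id, fish_gene_id, score,
    rbh, support, accepted``; accepted rows form a fish->human function.
    Deterministic: ordering is fixed by ids, not input order.
    """
    hidx, fidx = _GeneIndex(human_genes), _GeneIndex(fish_genes)
    sim = similarity[
        similarity["human_gene_id"].map(hidx.known)
        & similarity["fish_gene_id"].map(fidx.known)
    ]
    if sim.empty:
        return pd.DataFrame(
            columns=["human_gene_id", "fish_gene_id", "score", "rbh", "support", "accepted"]
        )
    rbh_pairs = {
        (p.human_gene_id, p.fish_gene_id) for p in reciprocal_best_hits(sim)
    }
    best_f = sim.groupby("fish_gene_id")["score"].max()

    candidates: dict[str, list[tuple[str, float]]] = {}
    for r in sim.itertuples(index=False):
        if r.score >= tie_ratio * best_f[r.fish_gene_id]:
            candidates.setdefault(r.fish_gene_id, []).append(
                (r.human_gene_id, float(r.score))
            )
    for fish_id in candidates:
        candidates[fish_id].sort(key=lambda t: (-t[1], t[0]))

    accepted: dict[str, tuple[str, float, bool, int]] = {}
    pending: list[str] = []
    for fish_id in sorted(candidates):
        cands = candidates[fish_id]
        if len(cands) == 1 and (cands[0][0], fish_id) in rbh_pairs:
            accepted[fish_id] = (cands[0][0], cands[0][1], True, 0)
        else:
            pending.append(fish_id)

    # synteny context: accepted pairs + provisional best hits of the rest
    context = [(h, f) for f, (h, _, _, _) in accepted.items()]
    context += [(candidates[f][0][0], f) for f in pending]
    ctx_by_chrompair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h, f in context:
        key = (hidx.chrom[h], fidx.chrom[f])
        ctx_by_chrompair.setdefault(key, []).append(
            (hidx.ordinal[h], fidx.ordinal[f])
        )

    def support(h: str, f: str) -> int:
        ho, fo = hidx.ordinal[h], fidx.ordinal[f]
        pts = ctx_by_chrompair.get((hidx.chrom[h], fidx.chrom[f]), [])
        n = sum(
            1 for h2o, f2o in pts if abs(h2o - ho) <= window and abs(f2o - fo) <= window
        )
        # the pair itself is in the context iff it is f's provisional best
        if f in candidates and candidates[f][0][0] == h and (h, f) in context_set:
            n -= 1
        return n

    context_set = set(context)
    for fish_id in pending:
        scored = [
            (support(h, fish_id), s, h) for h, s in candidates[fish_id]
        ]
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        sup, score, h = scored[0]
        is_rbh = (h, fish_id) in rbh_pairs
        if is_rbh or sup > 0:
            accepted[fish_id] = (h, score, is_rbh, sup)

    rows = []
    for r in sim.sort_values(["fish_gene_id", "human_gene_id"]).itertuples(index=False):
        acc = accepted.get(r.fish_gene_id)
        is_acc = acc is not None and acc[0] == r.human_gene_id
        rows.append(
            (
                r.human_gene_id,
                r.fish_gene_id,
                float(r.score),
                (r.human_gene_id, r.fish_gene_id) in rbh_pairs,
                acc[3] if is_acc else 0,
                is_acc,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["human_gene_id", "fish_gene_id", "score", "rbh", "support", "accepted"],
    )


def synteny_blocks(
    table: pd.DataFrame,
    human_genes: Sequence[GeneRecord],
    fish_genes: Sequence[GeneRecord],
    window: int = 100,
) -> list[SyntenyBlock]:
    """Chain accepted pairs into conserved synteny blocks.

    Pairs are scanned in human (chromosome, ordinal) order; a pair extends
    the current block iff it is on the same chromosome pair and within
    ``window`` ordinals of the block's last pair in both species.
    Single-pair blocks are legitimate (size 1).
    """
    hidx, fidx = _GeneIndex(human_genes), _GeneIndex(fish_genes)
    acc = table[table["accepted"]]
    pairs = sorted(
        (
            (hidx.chrom[h], hidx.ordinal[h], fidx.chrom[f], fidx.ordinal[f], h, f)
            for h, f in zip(acc["human_gene_id"], acc["fish_gene_id"])
        ),
    )
    blocks: list[SyntenyBlock] = []
    last = None
    for hc, ho, fc, fo, h, f in pairs:
        if (
            last is not None
            and hc == last[0]
            and fc == last[2]
            and ho - last[1] <= window
            and abs(fo - last[3]) <= window
        ):
            blocks[-1].pairs.append((h, f))
        else:
            blocks.append(
                SyntenyBlock(
                    block_id=len(blocks), human_chromosome=hc, fish_chromosome=fc
                )
            )
            blocks[-1].pairs.append((h, f))
        last = (hc, ho, fc, fo)
    return blocks


def block_size_histogram(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """Histogram of block sizes binned 1, 2-10, 11-20, 21-30, ...

    Size-1 blocks are reported separately from the 2-10 bin.
    """
    sizes = np.array([b.size for b in blocks])
    labels, counts = ["1"], [int((sizes == 1).sum())]
    top = int(sizes.max()) if len(sizes) else 0
    lo = 2
    while lo <= top:
        hi = 10 if lo == 2 else lo + 9
        labels.append(f"{lo}-{hi}")
        counts.append(int(((sizes >= lo) & (sizes <= hi)).sum()))
        lo = hi + 1
    return pd.DataFrame({"size_bin": labels, "n_blocks": counts})
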