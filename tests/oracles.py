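"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain enumeration over table rows, sharing no
code path with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the exhaustive pairwise win rate, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    if not pos or not neg:
        raise ValueError("needs one positive and one negative")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def cosine_oracle(counts_a: dict, counts_b: dict) -> float:
    """Cosine over the explicit union vector, via plain arithmetic."""
    union = sorted(set(counts_a) | set(counts_b))
    if not union or not counts_a or not counts_b:
        return 0.0
    va = [counts_a.get(d, 0) for d in union]
    vb = [counts_b.get(d, 0) for d in union]
    dot = sum(x * y for x, y in zip(va, vb))
    na = math.sqrt(sum(x * x for x in va))
    nb = math.sqrt(sum(y * y for y in vb))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def hypergeom_tail_distribution(M: int, K: int, n: int) -> list[float]:
    """P(overlap >= k) for k = 0..n, by enumerating all C(M, n) draws.

    The universe is 0..M-1 and the annotated set is 0..K-1.
    """
    marked = set(range(K))
    total = 0
    count_by_k = [0] * (n + 1)
    for draw in itertools.combinations(range(M), n):
        total += 1
        count_by_k[len(marked.intersection(draw))] += 1
    tail = [0.0] * (n + 1)
    acc = 0
    for k in range(n, -1, -1):
        acc += count_by_k[k]
        tail[k] = acc / total
    return tail


def mcc_oracle(tp: int, tn: int, fp: int, fn: int) -> float:
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return num / den if den else 0.0


def brute_score_gene(g, lam: float, world, aggregation: str = "max"):
    """Explicit path enumeration over raw table rows.

    Returns ``{phenotype: (raw_ppi, raw_orth, final_score)}`` for every
    candidate of ``g``, mirroring the scorer's definition from first
    principles: scan every edge row, every ortholog row, every association
    row, every similarity row.
    """
    edges = [(e.a, e.b, e.combined_score) for e in world.net.edges()]
    assoc = world.assoc.records()
    orth_rows = [(p.gene, p.ortholog, p.domain_similarity) for p in world.orth.pairs()]
    sim_rows = world.phenet.edges()

    def sim(x, y) -> float:
        for a, b, s in sim_rows:
            if (a, b) == (x, y) or (a, b) == (y, x):
                return s
        return 0.0

    phenotypes = sorted(
        {ph for _, ph in assoc if ph.species == g.species}
        | {t for a, b, _ in sim_rows for t in (a, b) if t.species == g.species}
    )

    raw = {}
    for ph in phenotypes:
        s_ppi = 0.0
        for a, b, s in edges:
            partner = b if a == g else (a if b == g else None)
            if partner is not None and (partner, ph) in assoc:
                s_ppi += s
        s_orth = 0.0
        for x, y, ds in orth_rows:
            o = y if x == g else (x if y == g else None)
            if o is None or ds <= 0:
                continue
            sims = [sim(ph_o, ph) for gg, ph_o in assoc if gg == o]
            sims = [s for s in sims if s > 0]
            if not sims:
                continue
            s_orth += ds * (max(sims) if aggregation == "max" else sum(sims))
        if s_ppi > 0 or s_orth > 0:
            raw[ph] = (s_ppi, s_orth)

    if not raw:
        return {}
    max_p = max(v[0] for v in raw.values())
    max_o = max(v[1] for v in raw.values())
    combined = {}
    for ph, (p, o) in raw.items():
        np_ = p / max_p if max_p > 0 else 0.0
        no_ = o / max_o if max_o > 0 else 0.0
        combined[ph] = lam * np_ + (1 - lam) * no_
    top = max(combined.values())
    return {
        ph: (raw[ph][0], raw[ph][1], combined[ph] / top if top > 0 else 0.0)
        for ph in raw
    }


def best_cutoff_oracle(fpr, tpr, thresholds):
    """Exhaustive minimization of |TPR - (1 - FPR)|, earliest on ties."""
    best = None
    for i in range(len(fpr)):
        d = abs(tpr[i] - (1.0 - fpr[i]))
        if best is None or d < best[0] - 1e-15:
            best = (d, i)
    return thresholds[best[1]], best[1]
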