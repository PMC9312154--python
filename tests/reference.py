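"""Naive dict-and-loop reference implementation of the incentive walk.

Deliberately free of numpy and of the package's matrix machinery: plain
Python floats, dicts and loops, so it can serve as an independent oracle
for the optimized implementation on small networks.  It follows the same
published procedure — block-normalized transition matrix, restart walk
with incentives and degree penalties, entropy-guided belief propagation
after coverage — expressed in the most literal way possible.
"""

from __future__ import annotations

import math

from rwdir.hetnet import TYPE_ORDER, HeteroNetwork, Label

INCENTIVE = 0.1


def _block_W(net: HeteroNetwork, labels):
    ids = list(net.ids)
    typemap = dict(net.vertices)
    nbrs = {v: set() for v in ids}
    for u, v in net.edges:
        nbrs[u].add(v)
        nbrs[v].add(u)

    # block edge counts
    def count(a, b):
        c = 0
        for u, v in net.edges:
            tu, tv = typemap[u], typemap[v]
            if {tu, tv} == ({a, b} if a != b else {a}):
                c += 1
        return c

    MR, MI, LN = TYPE_ORDER
    ss, mm, nn = count(MR, MR), count(MI, MI), count(LN, LN)
    sm, sn, mn = count(MR, MI), count(MR, LN), count(MI, LN)
    lam = sm / (ss + mm) if ss + mm else 0.0
    dlt = sn / (ss + nn) if ss + nn else 0.0
    tht = mn / (mm + nn) if mm + nn else 0.0
    cross = {
        frozenset((MR, MI)): lam,
        frozenset((MR, LN)): dlt,
        frozenset((MI, LN)): tht,
    }

    def weight(t, u):
        if t == u:
            others = [x for x in TYPE_ORDER if x != t]
            return 1.0 - cross[frozenset((t, others[0]))] - cross[frozenset((t, others[1]))]
        return cross[frozenset((t, u))]

    W = {v: {} for v in ids}
    for v in ids:
        t = typemap[v]
        row = {}
        for u in TYPE_ORDER:
            block_nbrs = sorted(x for x in nbrs[v] if typemap[x] is u)
            if not block_nbrs:
                continue
            x = weight(t, u)
            for w in block_nbrs:
                row[w] = x / len(block_nbrs)
        total = sum(row.values())
        if total > 0:
            row = {k: val / total for k, val in row.items()}
        W[v] = row
    return W, nbrs


def reference_rwdir(net: HeteroNetwork, labels, *, alpha=0.85, tol=1e-6,
                    max_iter=1000, visit_eps=1e-12, stagnation_window=5,
                    use_entropy=True):
    """Rankings of the unlabeled vertices, computed the slow literal way."""
    ids = list(net.ids)
    index = {v: i for i, v in enumerate(ids)}
    lab = dict(zip(ids, labels))
    W, nbrs = _block_W(net, labels)
    deg = {v: len(nbrs[v]) for v in ids}

    related = [v for v in ids if lab[v] is Label.RELATED]
    if not related:
        raise ValueError("no related vertex")
    seed = max(related, key=lambda v: (deg[v], -index[v]))

    P0 = {v: 0.0 for v in ids}
    P0[seed] = 1.0
    Pt = dict(P0)
    visited = {seed}

    # connected component of the seed
    reachable = {seed}
    frontier = [seed]
    while frontier:
        nxt = []
        for v in frontier:
            for u in nbrs[v]:
                if u not in reachable:
                    reachable.add(u)
                    nxt.append(u)
        frontier = nxt

    has_unlabeled = any(lab[v] is Label.UNLABELED for v in ids)
    entropy_active = use_entropy and has_unlabeled
    m1 = None
    coverage = False
    stagnant = 0

    def step(Wcur, Pcur):
        out = {v: (1 - alpha) * P0[v] for v in ids}
        for v in ids:
            for u, p in Wcur[v].items():
                out[u] += alpha * Pcur[v] * p
        return out

    for t in range(1, max_iter + 1):
        prev = Pt
        Pt = step(W, prev)

        new = {v for v in ids
               if v not in visited and abs(Pt[v] - prev[v]) > visit_eps}
        if new:
            visited |= new
            stagnant = 0
        else:
            stagnant += 1

        for v in sorted(new, key=lambda x: index[x]):
            if lab[v] is Label.RELATED and P0[v] == 0.0:
                P0[v] = INCENTIVE
                z = sum(P0.values())
                P0 = {k: val / z for k, val in P0.items()}
        for v in ids:
            if lab[v] is Label.IRRELEVANT and v in visited and deg[v] > 0:
                Pt[v] /= deg[v]
                z = sum(Pt[u] for u in ids)
                Pt = {k: val / z for k, val in Pt.items()}

        if not coverage and (reachable <= visited or stagnant >= stagnation_window):
            coverage = True

        if entropy_active and coverage:
            if m1 is None:
                order = sorted(ids, key=lambda v: (-Pt[v], index[v]))
                rank = {v: r for r, v in enumerate(order, start=1)}
                h = len(ids)
                m1 = {}
                for v in ids:
                    if lab[v] is Label.RELATED:
                        m1[v] = 1.0
                    elif lab[v] is Label.IRRELEVANT:
                        m1[v] = 0.0
                    else:
                        m1[v] = (h - rank[v]) / h
            E = {}
            for v in ids:
                e = 0.0
                for p in (m1[v], 1.0 - m1[v]):
                    if p > 0:
                        e -= p * math.log2(p)
                E[v] = e
            Went = {}
            for v in ids:
                closed = sorted(nbrs[v] | {v}, key=lambda x: index[x])
                s = sum(E[u] for u in closed)
                if s > 0:
                    Went[v] = {u: E[u] / s for u in closed}
                else:
                    Went[v] = {u: 1.0 / len(closed) for u in closed}
            W = Went
            s1 = {v: 0.0 for v in ids}
            s2 = {v: 0.0 for v in ids}
            for v in ids:
                for u, p in W[v].items():
                    s1[u] += m1[v] * p
                    s2[u] += (1.0 - m1[v]) * p
            new_m1 = {}
            for v in ids:
                total = s1[v] + s2[v]
                new_m1[v] = s1[v] / total if total > 0 else m1[v]
                if lab[v] is Label.RELATED:
                    new_m1[v] = 1.0
                elif lab[v] is Label.IRRELEVANT:
                    new_m1[v] = 0.0
            m1 = new_m1

        delta = sum(abs(Pt[v] - prev[v]) for v in ids)
        if delta < tol and (not entropy_active or m1 is not None):
            break

    unlabeled = [v for v in ids if lab[v] is Label.UNLABELED]
    if use_entropy and m1 is not None:
        score = m1
    else:
        score = Pt
    ranking = sorted(unlabeled, key=lambda v: (-score[v], -Pt[v], index[v]))
    return ranking, {v: score[v] for v in unlabeled}
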