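"""Independent reference implementation of the CLEAR-MOT metrics for tests.

Deliberately written from the metric definitions with a different
algorithmic toolbox than the package: per-frame correspondence uses
brute-force enumeration over all injective assignments (so frames must stay
small), and the IDF1 identity pairing uses networkx max-weight matching
instead of the scipy Hungarian solver.  Conventions mirror the CLEAR
protocol: persistent correspondences are kept while within the match
radius; the residual is matched by minimal total distance among
maximum-cardinality assignments; gt ids are visited in sorted order.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def _dist(a, b):
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _brute_force_match(gt_items, hyp_items, radius):
    """Min-total-distance maximum-cardinality matching within the radius.

    gt_items / hyp_items: lists of (id, (x, y)).  Returns {gt_id: hyp_id}.
    """
    n_g, n_h = len(gt_items), len(hyp_items)
    best = {}
    best_key = (0, 0.0)  # (cardinality, -cost) maximized
    h_indices = list(range(n_h))
    for k in range(min(n_g, n_h), 0, -1):
        found = None
        for g_subset in itertools.combinations(range(n_g), k):
            for h_perm in itertools.permutations(h_indices, k):
                total = 0.0
                ok = True
                for gi, hi in zip(g_subset, h_perm):
                    d = _dist(gt_items[gi][1], hyp_items[hi][1])
                    if d > radius:
                        ok = False
                        break
                    total += d
                if ok and (found is None or total < found[0]):
                    found = (total, g_subset, h_perm)
        if found is not None:
            _, g_subset, h_perm = found
            return {gt_items[gi][0]: hyp_items[hi][0] for gi, hi in zip(g_subset, h_perm)}
    return {}


def clear_metrics(gt_records, hyp_records, match_radius):
    """Compute (mota, idf1, idsw, mt_percent, fp, fn) from record lists.

    gt_records / hyp_records: iterables of (frame, id, x, y).
    """
    gt_by_frame: dict = {}
    hyp_by_frame: dict = {}
    for f, i, x, y in gt_records:
        gt_by_frame.setdefault(f, []).append((i, (x, y)))
    for f, i, x, y in hyp_records:
        hyp_by_frame.setdefault(f, []).append((i, (x, y)))
    for table in (gt_by_frame, hyp_by_frame):
        for items in table.values():
            items.sort()

    n_gt = sum(len(v) for v in gt_by_frame.values())
    n_hyp = sum(len(v) for v in hyp_by_frame.values())
    frames = sorted(set(gt_by_frame) | set(hyp_by_frame))

    fp = fn = idsw = 0
    previous: dict = {}
    last_match: dict = {}
    matched_count: dict = {}
    for f in frames:
        gt_items = gt_by_frame.get(f, [])
        hyp_items = hyp_by_frame.get(f, [])
        hyp_pos = dict(hyp_items)
        # persistence: keep live pairings still within the radius
        taken = set()
        matches = {}
        residual_gt = []
        for g, pos in gt_items:
            h = previous.get(g)
            if h is not None and h in hyp_pos and h not in taken and _dist(pos, hyp_pos[h]) <= match_radius:
                matches[g] = h
                taken.add(h)
            else:
                residual_gt.append((g, pos))
        residual_hyp = [(h, p) for h, p in hyp_items if h not in taken]
        matches.update(_brute_force_match(residual_gt, residual_hyp, match_radius))

        fp += len(hyp_items) - len(matches)
        fn += len(gt_items) - len(matches)
        for g in sorted(matches):
            h = matches[g]
            if g in last_match and last_match[g] != h:
                idsw += 1
            last_match[g] = h
            matched_count[g] = matched_count.get(g, 0) + 1
        previous = dict(previous)
        previous.update(matches)

    mota = 1.0 - (fp + fn + idsw) / n_gt

    # IDF1: max-weight one-to-one identity pairing on co-location counts
    overlap: dict = {}
    for f in frames:
        for g, gpos in gt_by_frame.get(f, []):
            for h, hpos in hyp_by_frame.get(f, []):
                if _dist(gpos, hpos) <= match_radius:
                    overlap[(g, h)] = overlap.get((g, h), 0) + 1
    graph = nx.Graph()
    for (g, h), w in overlap.items():
        graph.add_edge(("gt", g), ("hyp", h), weight=w)
    pairing = nx.max_weight_matching(graph, maxcardinality=False)
    idtp = 0
    for a, b in pairing:
        g = a[1] if a[0] == "gt" else b[1]
        h = b[1] if a[0] == "gt" else a[1]
        idtp += overlap[(g, h)]
    idf1 = 2.0 * idtp / (n_gt + n_hyp) if (n_gt + n_hyp) else 0.0

    lifetimes: dict = {}
    for items in gt_by_frame.values():
        for g, _ in items:
            lifetimes[g] = lifetimes.get(g, 0) + 1
    mostly = sum(1 for g, life in lifetimes.items() if matched_count.get(g, 0) / life >= 0.8)
    mt_percent = 100.0 * mostly / len(lifetimes)

    return mota, idf1, idsw, mt_percent, fp, fn
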