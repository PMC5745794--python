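"""Hudson-style ancestral recombination graph for two-deme histories.

Each lineage carries a list of ancestral-material segments ``(left, right,
carriers)`` over the continuous sequence ``[0, L)``; ``carriers`` is a bitmask
of the sampled haplotypes that inherit from the lineage on that stretch.
Backwards in time, lineages coalesce within demes, recombine at rate
``r * span`` (span includes trapped non-ancestral material), and migrate
inside migration windows.  Material whose carrier set reaches the full sample
has found its MRCA and is dropped.

Mutations are laid down on the fly: over a waiting interval ``dt`` the
mutation opportunity is ``mu * dt * total_material``, and each mutation marks
the carriers of the segment it lands on — equivalent to Poisson mutations on
the marginal genealogies without materializing them.
"""

from __future__ import annotations

import numpy as np

from .models import DemographicModel

__all__ = ["simulate_arg_mutations"]


def _merge_segments(a, b, full_mask):
    """Union of two segment lists; fully coalesced material is dropped."""
    pts = sorted({s[0] for s in a} | {s[1] for s in a} | {s[0] for s in b} | {s[1] for s in b})
    out = []
    ia = ib = 0
    for lo, hi in zip(pts[:-1], pts[1:]):
        mask = 0
        while ia < len(a) and a[ia][1] <= lo:
            ia += 1
        if ia < len(a) and a[ia][0] <= lo < a[ia][1]:
            mask |= a[ia][2]
        while ib < len(b) and b[ib][1] <= lo:
            ib += 1
        if ib < len(b) and b[ib][0] <= lo < b[ib][1]:
            mask |= b[ib][2]
        if mask == 0 or mask == full_mask:
            continue
        if out and out[-1][1] == lo and out[-1][2] == mask:
            out[-1] = (out[-1][0], hi, mask)
        else:
            out.append((lo, hi, mask))
    return out


def _split_segments(segs, x):
    left, right = [], []
    for lo, hi, mask in segs:
        if hi <= x:
            left.append((lo, hi, mask))
        elif lo >= x:
            right.append((lo, hi, mask))
        else:
            left.append((lo, x, mask))
            right.append((x, hi, mask))
    return left, right


def simulate_arg_mutations(model: DemographicModel, n0: int, n1: int, length: int, rng):
    """Run the ARG and return mutations as ``(pos_bp, carrier_mask)`` pairs."""
    from .coalescent import flatten_demography  # local import avoids a cycle

    n = n0 + n1
    full_mask = (1 << n) - 1
    bk, N0, N1, m01, m10, merged = flatten_demography(model)
    mu = model.mutation_rate
    rr = model.recombination_rate

    # lineage: [segments, deme]
    lins = [[[(0.0, float(length), 1 << i)], 0 if i < n0 else 1] for i in range(n)]
    if merged[0] == 1:
        for l in lins:
            l[1] = 0
    raw_muts = []  # (continuous pos, mask)
    t = 0.0
    iv = 0

    def material(segs):
        return sum(hi - lo for lo, hi, _ in segs)

    def span(segs):
        return segs[-1][1] - segs[0][0]

    def drop_mutations(dt):
        tot = sum(material(l[0]) for l in lins)
        if tot <= 0 or mu <= 0:
            return
        k = rng.poisson(mu * dt * tot)
        if k == 0:
            return
        weights = np.array([material(l[0]) for l in lins])
        picks = rng.choice(len(lins), size=k, p=weights / weights.sum())
        for li in picks:
            segs = lins[li][0]
            w = np.array([hi - lo for lo, hi, _ in segs])
            si = rng.choice(len(segs), p=w / w.sum()) if len(segs) > 1 else 0
            lo, hi, mask = segs[si]
            raw_muts.append((rng.uniform(lo, hi), mask))

    while len(lins) > 1:
        while t >= bk[iv + 1]:
            iv += 1
            if merged[iv] == 1:
                for l in lins:
                    l[1] = 0
        k0 = sum(1 for l in lins if l[1] == 0)
        k1 = len(lins) - k0
        c0 = k0 * (k0 - 1) / 2.0 / (2.0 * N0[iv])
        c1 = 0.0 if merged[iv] else k1 * (k1 - 1) / 2.0 / (2.0 * N1[iv])
        rmig0 = 0.0 if merged[iv] else k0 * m01[iv]
        rmig1 = 0.0 if merged[iv] else k1 * m10[iv]
        spans = np.array([span(l[0]) for l in lins])
        rrec = rr * spans.sum()
        tot = c0 + c1 + rmig0 + rmig1 + rrec
        if tot <= 0:
            drop_mutations(bk[iv + 1] - t)
            t = bk[iv + 1]
            continue
        dt = rng.exponential(1.0 / tot)
        if t + dt >= bk[iv + 1]:
            drop_mutations(bk[iv + 1] - t)
            t = bk[iv + 1]
            continue
        drop_mutations(dt)
        t += dt
        u = rng.uniform(0, tot)
        if u < c0 + c1:
            d = 0 if u < c0 else 1
            idx = [i for i, l in enumerate(lins) if l[1] == d]
            ia, ib = rng.choice(len(idx), size=2, replace=False)
            a, b = idx[ia], idx[ib]
            segs = _merge_segments(lins[a][0], lins[b][0], full_mask)
            keep = [l for i, l in enumerate(lins) if i not in (a, b)]
            if segs:
                keep.append([segs, d])
            lins = keep
        elif u < c0 + c1 + rmig0 + rmig1:
            src = 0 if u < c0 + c1 + rmig0 else 1
            idx = [i for i, l in enumerate(lins) if l[1] == src]
            lins[idx[rng.integers(len(idx))]][1] = 1 - src
        else:
            # recombination: breakpoint uniform within the lineage's span
            w = (u - (c0 + c1 + rmig0 + rmig1)) / rr
            li = int(np.searchsorted(np.cumsum(spans), w, side="right"))
            li = min(li, len(lins) - 1)
            segs = lins[li][0]
            x = rng.uniform(segs[0][0], segs[-1][1])
            left, right = _split_segments(segs, x)
            if left and right:
                d = lins[li][1]
                lins[li] = [left, d]
                lins.append([right, d])

    return _discretize(raw_muts, length, rng)


def _discretize(raw_muts, length, rng):
    """Snap continuous positions to distinct integer bp (collisions re-drawn)."""
    used = set()
    out = []
    for pos, mask in raw_muts:
        bp = int(pos) + 1
        tries = 0
        while bp in used and tries < 100:
            bp = int(rng.integers(1, length + 1))
            tries += 1
        if bp in used:
            continue
        used.add(bp)
        out.append((bp, mask))
    return out
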