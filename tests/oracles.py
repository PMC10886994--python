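"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with explicit python loops and first-principles
formulas over plain records, deliberately avoiding the vectorized code paths
(and most library calls) the package itself uses.
"""

from __future__ import annotations

import math

import pandas as pd


def _mean(values) -> float:
    values = list(values)
    return sum(values) / len(values)


def _sample_sd(values) -> float:
    values = list(values)
    m = _mean(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def oracle_normalize(
    table: pd.DataFrame,
    method: str,
    features: list[str],
    external: pd.DataFrame | None = None,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Elementwise recomputation of every normalization method."""
    rows = table.to_dict("records")
    orig = [dict(r) for r in rows]  # pristine values for statistics
    subjects = sorted({r["subject_id"] for r in rows})

    def stat_rows(pred):
        return [r for r in orig if pred(r) and r["phase"] in ("baseline", "stabilization")]

    if method == "none":
        return table.copy()

    if method == "ibn":
        for sid in subjects:
            own = [r for r in rows if r["subject_id"] == sid]
            base = [r for r in own if r["phase"] == "baseline"]
            for f in features:
                mu = _mean(r[f] for r in base)
                for r in own:
                    r[f] = (r[f] - mu) / mu

    elif method in ("m2", "m4"):
        assert external is not None
        ext_rows = external.to_dict("records")
        for f in features:
            vals = [r[f] for r in ext_rows]
            mu = _mean(vals)
            denom = _sample_sd(vals) if method == "m2" else mu
            for r in rows:
                r[f] = (r[f] - mu) / denom

    elif method in ("zscore", "minmax", "decimal"):
        for f in features:
            vals = [r[f] for r in rows]
            if method == "zscore":
                mu, sd = _mean(vals), _sample_sd(vals)
                for r in rows:
                    r[f] = (r[f] - mu) / sd
            elif method == "minmax":
                lo, hi = min(vals), max(vals)
                for r in rows:
                    r[f] = (r[f] - lo) / (hi - lo)
            else:
                k = 0
                while max(abs(v) for v in vals) / 10**k >= 1.0:
                    k += 1
                for r in rows:
                    r[f] = r[f] / 10**k

    else:
        # LOSO-based methods: each subject transformed with the others' stats.
        for sid in subjects:
            own = [r for r in rows if r["subject_id"] == sid]
            held_in = stat_rows(lambda r, s=sid: r["subject_id"] != s)
            w = weights[sid] if weights is not None else None
            for f in features:
                vals = [r[f] for r in held_in]
                mu, sd = _mean(vals), _sample_sd(vals)
                for r in own:
                    x = r[f]
                    if method == "m1":
                        y = (x - mu) / sd
                    elif method == "m3":
                        y = (x - mu) / mu
                    elif method == "m5":
                        y = (x - mu) / sd / w
                    elif method == "m6":
                        y = (x - mu) / mu / w
                    elif method == "m7":
                        y = (x - mu) / mu
                        y = y * w if f in ("HR", "LVET") else y / w
                    else:
                        raise ValueError(method)
                    r[f] = y

    return pd.DataFrame(rows, index=table.index)


def oracle_auc(y_binary, scores) -> float:
    """Mann-Whitney AUC by exhaustive pair counting with half credit for ties."""
    pos = [s for y, s in zip(y_binary, scores) if y == 1]
    neg = [s for y, s in zip(y_binary, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_spearman_rho(a, b) -> float:
    """Spearman rho as the Pearson correlation of midranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    ra, rb = midranks(list(a)), midranks(list(b))
    ma, mb = _mean(ra), _mean(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb))
    return num / den
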