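"""Independent straight-line oracles used to cross-check the pipeline.

These are deliberately written with plain Python loops and the stdlib
``statistics`` module, sharing no code path with the package, so that
agreement is meaningful.
"""

from __future__ import annotations

import statistics


def naive_find(text: str, term: str) -> bool:
    """Substring search by explicit character comparison (no ``in``)."""
    n, m = len(text), len(term)
    if m == 0 or m > n:
        return False
    for start in range(n - m + 1):
        ok = True
        for j in range(m):
            if text[start + j] != term[j]:
                ok = False
                break
        if ok:
            return True
    return False


def brute_force_matches(text: str, categories: dict[str, list[str]]) -> bool:
    """Triple nested loop: one hit required from every category."""
    import unicodedata

    text = unicodedata.normalize("NFKC", text)
    for terms in categories.values():
        found = False
        for term in terms:
            if naive_find(text, unicodedata.normalize("NFKC", term)):
                found = True
                break
        if not found:
            return False
    return True


def straightline_index(
    A: list[list[float | None]], B: list[list[float | None]]
) -> list[float]:
    """Steps 2-5 of the index recipe in plain loops.

    ``A``/``B`` are newspaper-major matrices with ``None`` for missing
    cells.  Cells with B = 0 are dropped.  Returns the mean-100 index by
    month.
    """
    n_papers = len(A)
    n_months = len(A[0])
    # step 2: scaled frequencies
    X: list[list[float | None]] = []
    for i in range(n_papers):
        row: list[float | None] = []
        for t in range(n_months):
            if A[i][t] is None or B[i][t] is None or B[i][t] == 0:
                row.append(None)
            else:
                row.append(A[i][t] / B[i][t])
        X.append(row)
    # step 3: unit sample SD per newspaper
    Y: list[list[float | None]] = []
    for i in range(n_papers):
        obs = [x for x in X[i] if x is not None]
        sigma = statistics.stdev(obs)
        Y.append([None if x is None else x / sigma for x in X[i]])
    # step 4: cross-paper monthly mean over present cells
    Z: list[float] = []
    for t in range(n_months):
        col = [Y[i][t] for i in range(n_papers) if Y[i][t] is not None]
        Z.append(sum(col) / len(col))
    # step 5: normalize to mean 100
    M = sum(Z) / len(Z)
    return [z * 100.0 / M for z in Z]


def pearson_r(x: list[float], y: list[float]) -> float:
    """Pearson r from the covariance / SD definition, plain loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = (sum((a - mx) ** 2 for a in x) / (n - 1)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / (n - 1)) ** 0.5
    return cov / (sx * sy)
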