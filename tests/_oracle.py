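"""Naive reference implementations used as independent oracles in tests.

Deliberately written as plain per-indicator loops over the long response
table, with none of the vectorized machinery of the package, so that
agreement between the two is a meaningful check.
"""

import numpy as np

QD_OF = {
    "QD1": "QD1",
    "QD2": "QD2",
    "QD3A": "QD3",
    "QD3B": "QD3",
    "QD3C": "QD3",
    "QD3D": "QD3",
    "QD4": "QD4",
    "QD5": "QD5",
    "QD6": "QD6",
}


def oracle_fraction(answers):
    """Yes-share / graded mean over non-NA answers; None if all NA."""
    vals = []
    for a in answers:
        s = str(a).strip().lower()
        if s == "yes":
            vals.append(1.0)
        elif s == "no":
            vals.append(0.0)
        elif s == "na":
            continue
        else:
            vals.append(float(s))
    if not vals:
        return None
    return sum(vals) / len(vals)


def oracle_scorecard(catalog, responses, facility, year, weighted=True):
    """Per-QD and overall scores for one facility-year, loop by loop."""
    weight_of = dict(zip(catalog["id"], catalog["weight"]))
    section_of = dict(zip(catalog["id"], catalog["section"]))
    answers = {}
    sub = responses[(responses["facility"] == facility) & (responses["year"] == year)]
    for _, row in sub.iterrows():
        answers.setdefault(row["indicator"], []).append(row["answer"])

    by_qd = {}
    for ind, ans in sorted(answers.items()):
        if ind not in section_of:
            continue
        frac = oracle_fraction(ans)
        if frac is None:
            continue
        qd = QD_OF[section_of[ind]]
        w = float(weight_of[ind]) if weighted else 1.0
        by_qd.setdefault(qd, []).append((w, frac))

    qd_scores = {}
    for qd, pairs in by_qd.items():
        num = sum(w * f for w, f in pairs)
        den = sum(w for w, _ in pairs)
        qd_scores[qd] = 100.0 * num / den
    overall = float(np.mean(list(qd_scores.values()))) if qd_scores else None
    return qd_scores, overall
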