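"""Independent oracles used by the test suite.

These are deliberately written straight from the defining formulas with
plain Python loops, sharing no code with the package implementations they
check.
"""

import math

import numpy as np


def oracle_axis_features(series):
    """Per-axis features for one window axis, as a dict."""
    s = [float(v) for v in series]
    n = len(s)
    mean = sum(s) / n
    mx, mn = max(s), min(s)
    srt = sorted(s)
    if n % 2:
        med = srt[n // 2]
    else:
        med = 0.5 * (srt[n // 2 - 1] + srt[n // 2])
    if n > 1:
        var = sum((v - mean) ** 2 for v in s) / (n - 1)
    else:
        var = 0.0
    std = math.sqrt(var)
    rms = math.sqrt(sum(v * v for v in s) / n)
    # sign-change rate
    changes = 0
    for a, b in zip(s[:-1], s[1:]):
        sa = (a > 0) - (a < 0)
        sb = (b > 0) - (b < 0)
        if sa != sb:
            changes += 1
    zcr = changes / n
    # 16-bin histogram entropy, natural log
    counts, _ = np.histogram(np.asarray(s), bins=16)
    ent = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            ent -= p * math.log(p)
    if std > 0:
        skn = sum((v - mean) ** 3 for v in s) / n / std**3
        krt = sum((v - mean) ** 4 for v in s) / n / std**4
    else:
        skn = krt = 0.0
    mad = sum(abs(v - mean) for v in s) / n
    return {
        "amp": mx - mean,
        "med": med,
        "mean": mean,
        "max": mx,
        "min": mn,
        "var": var,
        "std": std,
        "rms": rms,
        "p2p": mx - mn,
        "zcr": zcr,
        "ent": ent,
        "skn": skn,
        "krt": krt,
        "rng": mx - mn,
        "mad": mad,
    }


def oracle_window_features(window):
    """The full 48-vector in feature-number order, independently coded."""
    window = [[float(v) for v in row] for row in window]
    n = len(window)
    axes = [[row[k] for row in window] for k in range(3)]
    per_axis = [oracle_axis_features(a) for a in axes]

    out = []
    for fam in ("amp", "med", "mean", "max", "min", "var", "std", "rms",
                "p2p", "zcr", "ent", "skn", "krt"):
        out.extend(per_axis[k][fam] for k in range(3))
    mag = sum(
        math.sqrt(x * x + y * y + z * z) for x, y, z in window
    ) / n
    out.append(mag)
    eng = sum(x * x + y * y + z * z for x, y, z in window)
    out.append(eng)
    out.extend(per_axis[k]["rng"] for k in range(3))
    ang = max(
        math.atan2(z, math.sqrt(x * x + y * y)) for x, y, z in window
    )
    out.append(ang)
    out.extend(per_axis[k]["mad"] for k in range(3))
    return np.array(out)


def oracle_one_vs_rest_metrics(counts):
    """Brute-force macro metrics from an l x l count matrix (rows true)."""
    counts = [[int(v) for v in row] for row in counts]
    l = len(counts)
    total = sum(sum(row) for row in counts)
    acc_terms, prec_terms, rec_terms, tpr_terms, tnr_terms = [], [], [], [], []
    for i in range(l):
        tp = counts[i][i]
        fn = sum(counts[i]) - tp
        fp = sum(counts[r][i] for r in range(l)) - tp
        tn = total - tp - fn - fp
        acc_terms.append((tp + tn) / (tp + tn + fp + fn))
        prec_terms.append(tp / (tp + fp) if tp + fp else 0.0)
        rec_terms.append(tp / (tp + fn) if tp + fn else 0.0)
        tpr_terms.append(tp / (tp + fn) if tp + fn else None)
        tnr_terms.append(tn / (tn + fp) if tn + fp else None)
    accuracy = sum(acc_terms) / l
    precision = sum(prec_terms) / l
    recall = sum(rec_terms) / l
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    balanced = None
    if all(v is not None for v in tpr_terms + tnr_terms):
        balanced = (sum(tpr_terms) + sum(tnr_terms)) / (2 * l)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "balanced_accuracy": balanced,
    }
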