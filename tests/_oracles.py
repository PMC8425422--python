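"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid the package's seed-index aligner and threshold
sweep: the aligner oracle scans every window of every allele on both
strands; the evaluation oracle enumerates every distinct threshold.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_force_align(read: str, records, max_mismatches: int) -> set[str]:
    """All-window Hamming scan over every allele, both strands."""
    hits: set[str] = set()
    for strand in (read, rc(read)):
        arr = np.frombuffer(strand.encode(), dtype=np.uint8)
        L = arr.shape[0]
        for rec in records:
            if rec.allele_name in hits:
                continue
            s = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
            for start in range(s.shape[0] - L + 1):
                if np.count_nonzero(s[start:start + L] != arr) <= max_mismatches:
                    hits.add(rec.allele_name)
                    break
    return hits


def brute_force_best_f1(percents: dict[tuple[str, str], float],
                        labels: dict[str, str]) -> float:
    """Best F1 over every distinct threshold, by exhaustive enumeration."""
    thresholds = sorted(set(percents.values()) | {0.0, 100.0})
    best = 0.0
    for t in thresholds:
        tp = fp = fn = 0
        for (a, b), pct in percents.items():
            pred = pct >= t
            same = labels[a] == labels[b]
            if pred and same:
                tp += 1
            elif pred and not same:
                fp += 1
            elif not pred and same:
                fn += 1
        if tp == 0:
            f1 = 0.0
        else:
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            f1 = 2 * precision * recall / (precision + recall)
        best = max(best, f1)
    return best
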