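"""Mutability indices: observed vs composition-expected k-mer mutation counts.

The mutability index (MI) of a k-mer is the number of observed mutations
attributed to it divided by the count expected if mutations fell uniformly,
i.e. the k-mer's relative frequency in the (unmasked) germline times the
total observed mutations.  MI = 1 means unbiased targeting; hotspots exceed
1, cold spots fall below.  Per-k-mer significance uses a two-cell df=1
chi-square goodness-of-fit of (at the k-mer, elsewhere) against expectation.

Attribution convention (documented, configurable for dinucleotides): a
mutation at position i belongs to the mononucleotide at i, the dinucleotide
starting at i (falling back to the one ending at i for the last position),
and the trinucleotide centred on i (edge positions excluded).  This keeps the
observed total conserved so expected and observed remain comparable.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import pandas as pd
from scipy.stats import chi2 as chi2_dist

from shmprof._util import masked_positions


def kmer_composition(reference: str, k: int, masked_spans=()) -> dict:
    """Relative frequencies of overlapping k-mers over unmasked positions.

    A k-mer window counts only if fully unmasked and free of N.  Frequencies
    sum to 1.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if len(reference) < k:
        raise ValueError("reference shorter than k")
    masked = masked_positions(len(reference), masked_spans)
    counts: Counter = Counter()
    for i in range(len(reference) - k + 1):
        if any(i + j in masked for j in range(k)):
            continue
        kmer = reference[i:i + k]
        if "N" in kmer:
            continue
        counts[kmer] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("reference fully masked; no k-mer windows")
    return {kmer: n / total for kmer, n in sorted(counts.items())}


def expected_mutations(frequencies: dict, total_observed: float) -> dict:
    """Expected mutations per k-mer under unbiased targeting:
    frequency x total observed.  Conserves the total by construction."""
    if total_observed < 0:
        raise ValueError("total_observed must be >= 0")
    s = sum(frequencies.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1 (got {s})")
    return {kmer: freq * total_observed for kmer, freq in frequencies.items()}


def mutability_index(observed: float, expected: float):
    """MI = observed / expected. Returns None (NA) when both are zero and
    raises when mutations are attributed to an absent k-mer."""
    if expected == 0:
        if observed == 0:
            return None
        raise ValueError("observed mutations at a k-mer with zero expectation "
                         "(unattributable)")
    return observed / expected


def hazard_enrichment(mi: float, frequency: float):
    """Per-site hazard multiplier implied by an observed MI.

    Because the expected counts are normalised to the *observed* total, a
    hotspot's MI is compressed below its true per-site rate multiplier b:
    a k-mer with composition share f and multiplier b (others 1) yields

        MI = b / (f*b + 1 - f)   <=>   b = MI*(1 - f) / (1 - MI*f)

    so MI < b whenever f > 0.  This inverts the compression; returns None
    when MI*f >= 1 (MI at or beyond the attainable maximum 1/f).
    """
    if not 0 < frequency < 1:
        raise ValueError("frequency must be in (0,1)")
    denom = 1.0 - mi * frequency
    if denom <= 0:
        return None
    return mi * (1.0 - frequency) / denom


def attribute_mutations(records: Sequence, reference: str, k: int,
                        masked_spans=(), dinucleotide_rule: str = "start") -> Counter:
    """Observed mutation counts per germline k-mer (substitutions only).

    k=1: the germline base.  k=2: the dinucleotide starting at the mutated
    position (the one ending there for the final position); rule
    ``"both"`` instead credits both overlapping dinucleotides (total doubles
    except at edges).  k=3: the trinucleotide centred on the position; edge
    positions are excluded.  Events in masked spans or touching N are skipped.
    """
    if dinucleotide_rule not in ("start", "both"):
        raise ValueError("dinucleotide_rule must be 'start' or 'both'")
    masked = masked_positions(len(reference), masked_spans)
    counts: Counter = Counter()
    for rec in records:
        if rec.event_class != "substitution":
            continue
        i = rec.position
        if not 0 <= i < len(reference):
            raise ValueError(f"record position {i} outside reference")
        if i in masked:
            continue
        if k == 1:
            kmer = reference[i]
            if kmer != "N":
                counts[kmer] += 1
        elif k == 2:
            windows = []
            if dinucleotide_rule == "both":
                if i + 1 < len(reference):
                    windows.append(i)
                if i - 1 >= 0:
                    windows.append(i - 1)
            else:
                windows.append(i if i + 1 < len(reference) else i - 1)
            for w in windows:
                kmer = reference[w:w + 2]
                if "N" not in kmer and not ({w, w + 1} & masked):
                    counts[kmer] += 1
        else:
            if i == 0 or i == len(reference) - 1:
                continue  # no centred trinucleotide at the edges
            kmer = reference[i - 1:i + 2]
            if "N" not in kmer and not ({i - 1, i, i + 1} & masked):
                counts[kmer] += 1
    return counts


def chi_square_mi(observed: float, expected: float, total_observed: float):
    """Two-cell df=1 goodness-of-fit of (at k-mer, elsewhere) vs expectation.

    chi2 = (obs-exp)^2/exp + ((total-obs)-(total-exp))^2/(total-exp).
    Returns (chi2, p).  Degenerate when expected equals the total.
    """
    if expected <= 0 or expected >= total_observed:
        return None, None
    if observed > total_observed:
        raise ValueError("observed exceeds total_observed")
    rest_obs = total_observed - observed
    rest_exp = total_observed - expected
    chi2 = (observed - expected) ** 2 / expected + (rest_obs - rest_exp) ** 2 / rest_exp
    p = float(chi2_dist.sf(chi2, df=1))
    return chi2, p


def mutability_table(records: Sequence, reference: str, k: int,
                     masked_spans=(), dinucleotide_rule: str = "start") -> pd.DataFrame:
    """Full MI table for one k: kmer, observed, expected, MI, chi2, p and
    significance flags at alpha = 0.01 and 0.001.

    The expected counts are normalised to the total of *attributable*
    observations at this k, so sum(expected) == sum(observed).
    """
    observed = attribute_mutations(records, reference, k, masked_spans,
                                   dinucleotide_rule=dinucleotide_rule)
    frequencies = kmer_composition(reference, k, masked_spans)
    total = sum(observed.values())
    expected = expected_mutations(frequencies, total)
    rows = []
    for kmer in sorted(set(frequencies) | set(observed)):
        obs = observed.get(kmer, 0)
        exp = expected.get(kmer, 0.0)
        mi = mutability_index(obs, exp) if exp > 0 else (None if obs == 0 else float("inf"))
        chi2, p = chi_square_mi(obs, exp, total) if exp > 0 else (None, None)
        rows.append({
            "kmer": kmer, "observed": obs, "expected": exp,
            "MI": mi, "chi2": chi2, "p": p,
            "sig_0.01": bool(p is not None and p < 0.01),
            "sig_0.001": bool(p is not None and p < 0.001),
        })
    return pd.DataFrame(rows)
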