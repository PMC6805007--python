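"""Sex-chromosome genotype inference over pedigrees and maternal symbiont
transmission statistics.

Individuals carry XX, XY or YY sex chromosomes.  Phenotypic sex follows the
feminization rule: an individual is female iff it carries the symbiont or is
XX.  Observations per individual are a Y-marker PCR (amplification = carries
at least one Y, i.e. XY or YY; no amplification = XX), infection status, and
optionally a qPCR dose ratio (2^-dCt of a Y-specific marker against an
autosomal reference; ~0 for XX, ~0.5 for XY, ~1 for YY).

Genotype inference runs Mendelian constraint propagation over the pedigree
graph to a fixed point, then resolves remaining XY-vs-YY ambiguity in parents
by a segregation likelihood over the offspring marker classes, making a
definite call only when one candidate dominates by a Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rank_stats import RankTestResult, dunn_posthoc, kruskal_wallis

__all__ = [
    "GenotypeCall",
    "classify_qpcr",
    "infer_genotypes",
    "transmission_rate",
    "transmission_group_test",
    "MendelianInconsistencyError",
]

GENOTYPES = ("XX", "XY", "YY")
_GAMETES = {"XX": frozenset("X"), "XY": frozenset("XY"), "YY": frozenset("Y")}
#: probability a gamete from each genotype carries X
_P_X = {"XX": 1.0, "XY": 0.5, "YY": 0.0}

# qPCR dose bands: midpoint cuts around the expected ratios 0, 0.5 and 1
QPCR_BANDS = (0.25, 0.75, 1.5)


class MendelianInconsistencyError(ValueError):
    """Observed genotypes in a parent-offspring triangle cannot be reconciled
    with Mendelian segregation."""


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    call: str  # XX | XY | YY | XY_or_YY | unknown
    basis: str  # marker | qpcr | inference
    trace: str = ""


def classify_qpcr(ratio: float, bands: tuple[float, float, float] = QPCR_BANDS) -> str:
    """Genotype from a Y/autosome qPCR dose ratio.

    XX below the first cut, XY between the first and second, YY between the
    second and third; values beyond the last cut are flagged unknown.
    """
    if ratio < 0:
        raise ValueError(f"negative qPCR ratio {ratio}")
    lo, mid, hi = bands
    if ratio < lo:
        return "XX"
    if ratio < mid:
        return "XY"
    if ratio <= hi:
        return "YY"
    return "unknown"


_REQUIRED_COLS = {"individual_id", "mother_id", "father_id", "sex", "y_marker", "wolbachia"}


def _initial_candidates(row: pd.Series) -> tuple[set[str], list[str]]:
    cands = set(GENOTYPES)
    notes = []
    if row["sex"] == "male":
        cands &= {"XY", "YY"}
        notes.append("male phenotype excludes XX")
    elif row["sex"] == "female" and row["wolbachia"] == "uninfected":
        cands &= {"XX"}
        notes.append("uninfected female must be XX (feminization rule)")
    if row["y_marker"] == "positive":
        cands &= {"XY", "YY"}
        notes.append("Y-marker amplification excludes XX")
    elif row["y_marker"] == "negative":
        cands &= {"XX"}
        notes.append("no Y-marker amplification: XX")
    ratio = row.get("qpcr_ratio")
    if ratio is not None and not pd.isna(ratio):
        q = classify_qpcr(float(ratio))
        if q != "unknown":
            cands &= {q}
            notes.append(f"qPCR ratio {float(ratio):.3g} -> {q}")
        else:
            notes.append(f"qPCR ratio {float(ratio):.3g} out of band, ignored")
    return cands, notes


def _child_feasible(child_g: str, mother_c: set[str], father_c: set[str]) -> bool:
    need = sorted(child_g)  # e.g. ['X','Y']
    for gm in {g for m in mother_c for g in _GAMETES[m]}:
        for gf in {g for f in father_c for g in _GAMETES[f]}:
            if sorted(gm + gf) == need:
                return True
    return False


def _parent_feasible(g: str, other_c: set[str], child_c: set[str]) -> bool:
    for c in child_c:
        if _child_feasible(c, {g}, other_c):
            return True
    return False


def infer_genotypes(
    pedigree: pd.DataFrame, bayes_factor: float = 100.0
) -> tuple[pd.DataFrame, list[str]]:
    """Infer XX/XY/YY genotype calls for every pedigree member.

    Returns (calls table, inconsistency reports).  Calls carry a derivation
    trace; ambiguity that survives propagation and the likelihood step is
    reported as ``XY_or_YY`` (Y-marker positive) or ``unknown``, never
    guessed.

    Parameters
    ----------
    pedigree
        Table with columns individual_id, mother_id, father_id, sex
        (male/female), y_marker (positive/negative/untested), wolbachia
        (infected/uninfected/untested) and optionally qpcr_ratio.
    bayes_factor
        Dominance ratio one candidate's segregation likelihood must reach
        over the runner-up before an ambiguous parent is called definitely.
    """
    missing = _REQUIRED_COLS - set(pedigree.columns)
    if missing:
        raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
    ids = list(pedigree["individual_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual_id in pedigree")
    rows = {r["individual_id"]: r for _, r in pedigree.iterrows()}
    cands: dict[str, set[str]] = {}
    traces: dict[str, list[str]] = {}
    for iid, row in rows.items():
        c, notes = _initial_candidates(row)
        cands[iid] = c
        traces[iid] = notes
    children_of: dict[str, list[str]] = {iid: [] for iid in ids}
    parents_of: dict[str, tuple[str | None, str | None]] = {}
    for iid, row in rows.items():
        mid = row["mother_id"] if pd.notna(row["mother_id"]) and row["mother_id"] else None
        fid = row["father_id"] if pd.notna(row["father_id"]) and row["father_id"] else None
        parents_of[iid] = (mid, fid)
        for p in (mid, fid):
            if p is not None:
                if p not in rows:
                    raise ValueError(f"parent {p!r} of {iid!r} not in pedigree")
                children_of[p].append(iid)

    inconsistencies: list[str] = []

    # constraint propagation to a fixed point
    changed = True
    while changed:
        changed = False
        for iid in ids:
            mid, fid = parents_of[iid]
            if mid is None or fid is None:
                continue
            mc, fc = cands[mid], cands[fid]
            if not mc or not fc:
                continue
            keep = {g for g in cands[iid] if _child_feasible(g, mc, fc)}
            if keep != cands[iid]:
                if not keep:
                    inconsistencies.append(
                        f"Mendelian inconsistency: offspring {iid} "
                        f"(candidates {sorted(cands[iid])}) incompatible with "
                        f"mother {mid} {sorted(mc)} x father {fid} {sorted(fc)}"
                    )
                else:
                    traces[iid].append(
                        f"narrowed to {sorted(keep)} by parents {mid} x {fid}"
                    )
                cands[iid] = keep
                changed = True
        for pid in ids:
            kids = children_of[pid]
            if not kids or not cands[pid]:
                continue
            for kid in kids:
                mid, fid = parents_of[kid]
                other = fid if pid == mid else mid
                other_c = cands[other] if other is not None else set(GENOTYPES)
                if not cands[kid] or not other_c:
                    continue
                keep = {g for g in cands[pid] if _parent_feasible(g, other_c, cands[kid])}
                if keep != cands[pid]:
                    if not keep:
                        inconsistencies.append(
                            f"Mendelian inconsistency: parent {pid} "
                            f"(candidates {sorted(cands[pid])}) incompatible with "
                            f"offspring {kid} {sorted(cands[kid])}"
                        )
                    else:
                        traces[pid].append(
                            f"narrowed to {sorted(keep)} by offspring {kid}"
                        )
                    cands[pid] = keep
                    changed = True

    # segregation likelihood for parents still ambiguous; the co-parent is
    # profiled out (likelihood maximized over its candidates, jointly across
    # the children it shares with this parent), so an ambiguous mate can
    # never be blamed on the focal parent
    for pid in ids:
        if len(cands[pid]) < 2 or not children_of[pid]:
            continue
        by_mate: dict[str | None, list[str]] = {}
        for kid in children_of[pid]:
            mid, fid = parents_of[kid]
            other = fid if pid == mid else mid
            by_mate.setdefault(other, []).append(kid)
        loglik: dict[str, float] = {}
        for g in cands[pid]:
            ll = 0.0
            informative = 0
            for other, kids in by_mate.items():
                other_c = cands[other] if other is not None else set(GENOTYPES)
                if not other_c:
                    continue
                best = -np.inf
                best_n = 0
                for o in sorted(other_c):
                    mate_ll = 0.0
                    mate_n = 0
                    for kid in kids:
                        marker = rows[kid]["y_marker"]
                        if marker not in ("positive", "negative"):
                            continue
                        p_xx = _P_X[g] * _P_X[o]
                        p_obs = p_xx if marker == "negative" else 1.0 - p_xx
                        if p_obs <= 0.0:
                            mate_ll = -np.inf
                            break
                        mate_ll += float(np.log(p_obs))
                        mate_n += 1
                    if mate_ll > best:
                        best, best_n = mate_ll, mate_n
                if np.isfinite(best):
                    ll += best
                    informative += best_n
            if informative:
                loglik[g] = ll
        if len(loglik) < 2:
            continue
        ordered = sorted(loglik, key=loglik.get, reverse=True)
        best, second = ordered[0], ordered[1]
        log_bf = loglik[best] - loglik[second]
        if log_bf >= np.log(bayes_factor):
            cands[pid] = {best}
            traces[pid].append(
                f"segregation likelihood over {len(children_of[pid])} offspring: "
                f"{best} dominates {second} by Bayes factor "
                f"{np.exp(min(log_bf, 700)):.3g}"
            )

    calls = []
    for iid in ids:
        c = cands[iid]
        row = rows[iid]
        if len(c) == 1:
            call = next(iter(c))
            if row["y_marker"] == "negative" and call == "XX":
                basis = "marker"
            elif pd.notna(row.get("qpcr_ratio", np.nan)) and classify_qpcr(
                float(row["qpcr_ratio"])
            ) == call:
                basis = "qpcr"
            else:
                basis = "inference"
        elif c == {"XY", "YY"}:
            call, basis = "XY_or_YY", "marker" if row["y_marker"] == "positive" else "inference"
        elif not c:
            call, basis = "unknown", "inference"
        else:
            call, basis = "unknown", "inference"
        calls.append(
            GenotypeCall(individual_id=iid, call=call, basis=basis,
                         trace="; ".join(traces[iid]))
        )
    table = pd.DataFrame([c.__dict__ for c in calls])
    return table, inconsistencies


def transmission_rate(
    progeny_size: int,
    n_females: int,
    tested_females: int,
    infected_females: int,
) -> tuple[float, float | None]:
    """Weighted symbiont frequency in a progeny.

    frequency = (females / progeny size) * (infected / tested females),
    i.e. the infection frequency among tested females weighted by the female
    proportion of the brood (males never carry the symbiont).  Returns the
    exact fraction and the display percentage (rounded half-to-even to an
    integer); an all-male progeny is 0 without needing tested females, and a
    progeny with untested females has undefined frequency (None display,
    NaN fraction).
    """
    if not 0 <= tested_females <= n_females <= progeny_size:
        raise ValueError("need tested_females <= n_females <= progeny_size")
    if infected_females > tested_females:
        raise ValueError("infected_females cannot exceed tested_females")
    if n_females == 0:
        return 0.0, 0.0
    if tested_females == 0:
        return float("nan"), None
    frac = (n_females / progeny_size) * (infected_females / tested_females)
    return frac, float(round(frac * 100.0))


FAMILY_COLS = [
    "progeny_id",
    "mother_genotype",
    "father_genotype",
    "progeny_size",
    "n_females",
    "males_tested",
    "males_infected",
    "females_tested",
    "females_infected",
]


def family_transmission_table(families: pd.DataFrame) -> pd.DataFrame:
    """Add exact and display transmission frequencies and total tested counts
    to a family summary table."""
    missing = set(FAMILY_COLS) - set(families.columns)
    if missing:
        raise ValueError(f"family table missing columns: {sorted(missing)}")
    out = families.copy()
    fracs, pcts = [], []
    for _, r in out.iterrows():
        frac, pct = transmission_rate(
            int(r["progeny_size"]), int(r["n_females"]),
            int(r["females_tested"]), int(r["females_infected"]),
        )
        fracs.append(frac)
        pcts.append(pct)
    out["transmission_frac"] = fracs
    out["transmission_pct"] = pcts
    out["n_tested"] = out["males_tested"] + out["females_tested"]
    return out


def transmission_group_test(
    families: pd.DataFrame,
    min_tested: int | None = None,
    value: str = "transmission_frac",
) -> dict:
    """Kruskal-Wallis test of a per-family quantity across maternal genotypes,
    with Dunn pairwise post hocs.

    ``min_tested`` keeps only families in which at least that many
    individuals were tested for infection.  ``value`` selects the tested
    quantity (transmission fraction by default; e.g. ``progeny_size`` for the
    brood-size control analysis).
    """
    table = families if "transmission_frac" in families.columns else family_transmission_table(families)
    if min_tested is not None:
        table = table[table["n_tested"] >= min_tested]
    groups, labels = [], []
    for g, sub in table.groupby("mother_genotype"):
        if len(sub):
            groups.append(sub[value].to_numpy(dtype=float))
            labels.append(g)
    if len(groups) < 2:
        raise ValueError("need families from at least two maternal genotypes")
    kw: RankTestResult = kruskal_wallis(groups)
    dunn = dunn_posthoc(groups, labels=labels)
    return dict(
        kruskal=kw,
        dunn=dunn,
        n_families=int(len(table)),
        group_sizes={l: int(len(g)) for l, g in zip(labels, groups)},
        value=value,
    )
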