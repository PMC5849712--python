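"""Cross-species matching of AS events on the shared reference.

Because every species is aligned to the same reference genome, orthology
reduces to gene-id identity and two events are the *same* event when
their signatures — gene, event type and exact genomic coordinates
(including the reference intron for AltD/AltA/AltP) — are equal. An
evolutionarily conserved AS (ECAS) event is a signature observed in at
least two species; events seen in one species only are non-ECAS.

An optional ±k bp tolerance relaxes the "same position" rule for the
shifted boundaries of Alt events (default 0: exact equality); matching
under tolerance is transitive-closure clustering of boundary positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from ecas_splice.as_caller import ALTA, ALTD, ALTP, ASEvent


@dataclass(frozen=True)
class ECASRecord:
    signature: tuple
    species_set: frozenset[str]
    events: tuple[ASEvent, ...]

    @property
    def is_ecas(self) -> bool:
        return len(self.species_set) >= 2

    @property
    def gene_id(self) -> str:
        return self.signature[0]

    @property
    def event_type(self) -> str:
        return self.signature[1]


def _cluster_with_tolerance(
    events: list[ASEvent], tolerance: int
) -> dict[tuple, list[ASEvent]]:
    """Union-find clustering of Alt events whose boundaries agree within ±tolerance."""
    parent = list(range(len(events)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i, j in combinations(range(len(events)), 2):
        a, b = events[i], events[j]
        (a_s, a_e), (b_s, b_e) = a.intervals[0], b.intervals[0]
        if abs(a_s - b_s) <= tolerance and abs(a_e - b_e) <= tolerance:
            union(i, j)

    clusters: dict[int, list[ASEvent]] = {}
    for i in range(len(events)):
        clusters.setdefault(find(i), []).append(events[i])
    out = {}
    for members in clusters.values():
        rep = min(members, key=lambda e: e.intervals)  # deterministic representative
        out[rep.signature] = members
    return out


def build_signatures(
    events_by_species: dict[str, list[ASEvent]], tolerance: int = 0
) -> list[ECASRecord]:
    """Group all species' events by signature; deterministic output order."""
    seen_species = list(events_by_species)
    if len(seen_species) != len(set(seen_species)):
        raise ValueError("duplicate species_id")

    all_events: list[ASEvent] = []
    for species, events in events_by_species.items():
        for e in events:
            if e.species_id != species:
                e = ASEvent(
                    species_id=species,
                    gene_id=e.gene_id,
                    event_type=e.event_type,
                    intervals=e.intervals,
                    event_length=e.event_length,
                    region=e.region,
                    ref_junction=e.ref_junction,
                    contig_id=e.contig_id,
                )
            all_events.append(e)

    grouped: dict[tuple, list[ASEvent]] = {}
    if tolerance == 0:
        for e in all_events:
            grouped.setdefault(e.signature, []).append(e)
    else:
        exact_types: dict[tuple, list[ASEvent]] = {}
        alt_groups: dict[tuple, list[ASEvent]] = {}
        for e in all_events:
            if e.event_type in (ALTD, ALTA, ALTP):
                alt_groups.setdefault((e.gene_id, e.event_type, e.ref_junction), []).append(e)
            else:
                exact_types.setdefault(e.signature, []).append(e)
        grouped.update(exact_types)
        for members in alt_groups.values():
            grouped.update(_cluster_with_tolerance(members, tolerance))

    records = [
        ECASRecord(
            signature=sig,
            species_set=frozenset(e.species_id for e in members),
            events=tuple(sorted(members, key=lambda e: e.species_id)),
        )
        for sig, members in grouped.items()
    ]
    records.sort(key=lambda r: (r.gene_id, r.event_type, r.signature[2]))
    return records


def sharing_stats(records: list[ECASRecord], species: list[str]) -> pd.DataFrame:
    """Pairwise/triple/quadruple sharing counts and proportions.

    For a species group the shared count is the number of signatures
    present in every member; the proportion normalizes by the union of
    the group members' signature sets (Jaccard), printed as a percentage
    truncated to two decimals (the convention the reported shares follow).
    """
    if len(species) < 2:
        raise ValueError("need at least two species")
    sig_sets = {
        s: {r.signature for r in records if s in r.species_set} for s in species
    }
    rows = []
    for k in range(2, len(species) + 1):
        for group in combinations(species, k):
            shared = set.intersection(*(sig_sets[s] for s in group))
            union = set.union(*(sig_sets[s] for s in group))
            shared_genes = {sig[0] for sig in shared}
            rows.append(
                {
                    "group": "+".join(group),
                    "k": k,
                    "n_shared": len(shared),
                    "n_union": len(union),
                    "proportion_pct": math.floor(1e4 * len(shared) / len(union)) / 100.0
                    if union
                    else 0.0,
                    "n_shared_genes": len(shared_genes),
                }
            )
    return pd.DataFrame(rows)


def classify_events(records: list[ECASRecord]) -> tuple[list[ECASRecord], list[ECASRecord]]:
    """Partition records into (ECAS, non-ECAS); empty input → empty partition."""
    ecas = [r for r in records if r.is_ecas]
    non_ecas = [r for r in records if not r.is_ecas]
    return ecas, non_ecas


def ecas_gene_ids(records: list[ECASRecord]) -> set[str]:
    """Genes carrying at least one ECAS signature."""
    return {r.gene_id for r in records if r.is_ecas}


def ecas_table(records: list[ECASRecord], species: list[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "event_type": r.event_type,
                "intervals": ";".join(f"{s}-{e}" for s, e in r.signature[2]),
                "ref_junction": (
                    f"{r.signature[3][0]}-{r.signature[3][1]}" if r.signature[3] else ""
                ),
                "species_mask": "".join("1" if s in r.species_set else "0" for s in species),
                "n_species": len(r.species_set),
                "is_ecas": r.is_ecas,
            }
        )
    return pd.DataFrame(rows)


def upset_counts(records: list[ECASRecord], species: list[str]) -> pd.DataFrame:
    """Shared/private signature counts per species combination."""
    combo_counts: dict[frozenset, int] = {}
    for r in records:
        combo_counts[r.species_set] = combo_counts.get(r.species_set, 0) + 1
    rows = []
    for k in range(1, len(species) + 1):
        for group in combinations(species, k):
            fs = frozenset(group)
            rows.append(
                {"combination": "+".join(group), "k": k, "n_events": combo_counts.get(fs, 0)}
            )
    return pd.DataFrame(rows)
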