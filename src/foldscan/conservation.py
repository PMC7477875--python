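"""Conserved-hydrophobic-residue (CHR) and packing analysis.

A CHR site is an alignment column where the eight hydrophobic residues
(Ala, Phe, Ile, Leu, Met, Val, Tyr, Trp) make up more than 90% of the
sequences (gaps count in the denominator).  Conservation of predicted
compact regions is the per-site fraction of proteins whose regions cover
the site, with maximal runs above 70% reported as conserved spans.
Hydrophobic packing between two residues means closest heavy atoms
closer than 5 Å, discounting pairs within three residues along the
sequence.  Occurrence matrices summarize, across a protein set, how
often each labelled CHR–CHR packing contact appears.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .structure import CaStructure

log = logging.getLogger(__name__)

HYDROPHOBIC = frozenset("AFILMVYW")
GAP_CHARS = frozenset("-.")


def read_alignment(path, fmt: str = "fasta"):
    """Aligned sequences as a list of (id, sequence) (ragged -> error)."""
    aln = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def _check_alignment(msa) -> int:
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return lengths.pop()


def site_to_residue_maps(msa) -> list[dict[int, int]]:
    """Per sequence: alignment site (1-based) -> residue index (1-based)."""
    maps = []
    for _, seq in msa:
        m: dict[int, int] = {}
        r = 0
        for site, ch in enumerate(seq, start=1):
            if ch not in GAP_CHARS:
                r += 1
                m[site] = r
        maps.append(m)
    return maps


@dataclass
class ChrSite:
    site: int                       # alignment coordinate, 1-based
    fraction: float
    residues: dict[str, int] = field(default_factory=dict)  # seq id -> residue no.
    label: str = ""


def find_chr(msa, hydrophobic_set=HYDROPHOBIC, threshold: float = 0.9) -> list[ChrSite]:
    """Alignment sites whose hydrophobic fraction strictly exceeds the
    threshold; invariant to the order of sequences."""
    length = _check_alignment(msa)
    maps = site_to_residue_maps(msa)
    n_seq = len(msa)
    out = []
    for site in range(1, length + 1):
        col = [seq[site - 1] for _, seq in msa]
        frac = sum(c in hydrophobic_set for c in col) / n_seq
        if frac > threshold:
            residues = {sid: maps[k].get(site)
                        for k, (sid, _) in enumerate(msa)
                        if site in maps[k]}
            out.append(ChrSite(site=site, fraction=frac, residues=residues))
    return out


def label_chr_sites(sites: list[ChrSite], strand_annotation: dict) -> list[ChrSite]:
    """Attach strand labels (β1, β2N, …) from alignment-coordinate intervals.

    ``strand_annotation``: label -> [start_site, end_site] (inclusive).
    Two CHRs on one strand get N/C suffixes automatically if the supplied
    labels do not disambiguate them.
    """
    intervals = sorted(strand_annotation.items(), key=lambda kv: kv[1][0])
    by_label: dict[str, list[ChrSite]] = {}
    for s in sites:
        for label, (a, b) in intervals:
            if a <= s.site <= b:
                by_label.setdefault(label, []).append(s)
                break
    for label, group in by_label.items():
        group.sort(key=lambda s: s.site)
        if len(group) == 1:
            group[0].label = label
        else:
            suffixes = ["N", "C"] if len(group) == 2 else [str(i + 1) for i in range(len(group))]
            for s, suf in zip(group, suffixes):
                s.label = f"{label}{suf}"
    return sites


@dataclass
class RegionConservation:
    ratio: np.ndarray               # per alignment site, fraction of proteins covering it
    conserved_spans: list[tuple[int, int]]


def region_conservation(msa, regions_per_protein: dict[str, list[tuple[int, int]]],
                        threshold: float = 0.7) -> RegionConservation:
    """Per-site coverage of predicted compact regions across the set.

    Regions are given in each protein's own 1-based residue coordinates;
    a region end beyond the protein's length is an error naming it.
    Maximal runs of sites with ratio strictly above the threshold are the
    conserved predicted regions.
    """
    length = _check_alignment(msa)
    maps = site_to_residue_maps(msa)
    ids = [sid for sid, _ in msa]
    cover = np.zeros((len(msa), length), dtype=bool)
    for k, sid in enumerate(ids):
        regions = regions_per_protein.get(sid, [])
        n_res = len(maps[k])
        for (a, b) in regions:
            if not (1 <= a < b <= n_res):
                raise ValueError(f"region ({a}, {b}) outside protein {sid} "
                                 f"(length {n_res})")
        res_of = maps[k]
        for site, r in res_of.items():
            cover[k, site - 1] = any(a <= r <= b for a, b in regions)
    ratio = cover.mean(axis=0)
    spans = []
    in_run = False
    start = 0
    for i, v in enumerate(ratio > threshold):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            in_run = False
            spans.append((start + 1, i))
    if in_run:
        spans.append((start + 1, length))
    return RegionConservation(ratio=ratio, conserved_spans=spans)


@dataclass
class PackingContact:
    i: int                          # 1-based residue indices, i < j
    j: int
    min_distance: float


def packing_contacts(structure: CaStructure, residue_indices,
                     cutoff: float = 5.0, min_separation: int = 4) -> list[PackingContact]:
    """Hydrophobic packing among the listed residues (1-based indices).

    A pair packs when its closest heavy atoms are strictly closer than
    ``cutoff`` and the residues are at least ``min_separation`` apart
    along the sequence (pairs within three residues are discounted).
    Residues lacking heavy atoms are excluded with a warning.
    """
    idx = sorted(set(int(i) for i in residue_indices))
    usable = []
    for i in idx:
        res = structure.residues[i - 1]
        if not res.heavy_atoms:
            log.warning("residue %d has no heavy atoms; excluded", i)
            continue
        usable.append((i, np.asarray([a[1] for a in res.heavy_atoms])))
    out = []
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            i, xa = usable[a]
            j, xb = usable[b]
            if j - i < min_separation:
                continue
            d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2).min()
            if d < cutoff:
                out.append(PackingContact(i=i, j=j, min_distance=float(d)))
    return out


@dataclass
class OccurrenceMatrix:
    labels: list[str]
    percent: np.ndarray             # symmetric, [0, 100]; NaN where no protein has both CHRs
    full: np.ndarray                # bool: 100%
    frequent: np.ndarray            # bool: >= 95%

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for a, lab in enumerate(self.labels):
                row = "\t".join("" if np.isnan(v) else f"{v:.1f}"
                                for v in self.percent[a])
                fh.write(f"{lab}\t{row}\n")


def occurrence_matrix(contacts_by_protein: dict[str, set[tuple[str, str]]],
                      chr_present: dict[str, set[str]],
                      labels: list[str] | None = None,
                      frequent_threshold: float = 95.0) -> OccurrenceMatrix:
    """Percentage of proteins showing each labelled CHR–CHR contact.

    ``contacts_by_protein``: protein -> set of (label_a, label_b) pairs;
    ``chr_present``: protein -> set of CHR labels it actually has.  A
    protein missing either CHR of a pair is excluded from that cell's
    denominator (e.g. β7 contacts in a protein lacking β7).
    """
    if labels is None:
        labels = sorted({l for s in chr_present.values() for l in s})
    nl = len(labels)
    pct = np.full((nl, nl), np.nan)
    for a in range(nl):
        for b in range(a, nl):
            la, lb = labels[a], labels[b]
            denom = [p for p, present in chr_present.items()
                     if la in present and lb in present]
            if not denom:
                continue
            num = sum(
                1 for p in denom
                if (la, lb) in contacts_by_protein.get(p, set())
                or (lb, la) in contacts_by_protein.get(p, set()))
            pct[a, b] = pct[b, a] = 100.0 * num / len(denom)
    with np.errstate(invalid="ignore"):
        return OccurrenceMatrix(labels=list(labels), percent=pct,
                                full=pct == 100.0,
                                frequent=pct >= frequent_threshold)
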