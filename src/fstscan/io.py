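"""PLINK text PED/MAP reading and writing.

PED: one row per individual — family id (used here as the breed label),
individual id, four ignored pedigree/sex/phenotype columns, then two allele
columns per marker; "0 0" is a missing genotype. MAP: one row per marker —
chromosome, marker id, genetic distance (ignored), base-pair position.

Allele coding is deterministic: for each marker the counted allele
(``allele_a2``) is the lexicographically larger of the observed alleles, and
dosages count copies of it. The per-SNP Fst estimator is invariant to which
allele is counted, so this convention only fixes reporting. If a single
allele is observed, it becomes ``allele_a2`` and the other code stays "0";
such sample-monomorphic markers consequently do not round-trip their
(unobservable) second allele.
"""

from __future__ import annotations

import os

import numpy as np

from .dataset import MISSING, GenotypeDataset, Individual, MarkerRecord


class PedMapFormatError(ValueError):
    """Malformed PED/MAP content (bad token counts, alleles, genotypes)."""


def _read_map(map_path: str | os.PathLike) -> list[tuple[str, str, int]]:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PedMapFormatError(
                    f"{map_path}: line {ln}: expected 4 columns "
                    f"(chrom, id, cM, pos), got {len(parts)}"
                )
            chrom, marker_id, _cm, pos = parts
            try:
                pos_bp = int(pos)
            except ValueError as exc:
                raise PedMapFormatError(
                    f"{map_path}: line {ln}: non-integer position {pos!r}"
                ) from exc
            rows.append((chrom, marker_id, pos_bp))
    return rows


def read_ped_map(
    ped_path: str | os.PathLike, map_path: str | os.PathLike
) -> GenotypeDataset:
    """Load a PED/MAP pair into a :class:`GenotypeDataset`.

    Markers are sorted by (chrom, pos) on return, unmapped markers last.
    Half-called genotypes (one allele "0") and allele tokens longer than one
    character raise :class:`PedMapFormatError` rather than being masked.
    """
    map_rows = _read_map(map_path)
    n_markers = len(map_rows)

    individuals: list[Individual] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise PedMapFormatError(
                    f"{ped_path}: line {ln}: {len(parts) - 6} genotype columns "
                    f"for {n_markers} MAP markers (expected {2 * n_markers})"
                )
            breed, iid = parts[0], parts[1]
            individuals.append(Individual(individual_id=iid, breed=breed))
            allele_rows.append(np.array(parts[6:], dtype=object))

    n_ind = len(individuals)
    calls = np.full((n_ind, n_markers), MISSING, dtype=np.int8)
    markers: list[MarkerRecord] = []

    if n_ind:
        tokens = np.stack(allele_rows)  # (n_ind, 2*n_markers)
        bad_len = np.array([len(t) != 1 for t in tokens.ravel()]).reshape(tokens.shape)
        if bad_len.any():
            i, j = np.argwhere(bad_len)[0]
            raise PedMapFormatError(
                f"{ped_path}: individual {individuals[i].individual_id}: "
                f"allele token {tokens[i, j]!r} is not a single character"
            )
    else:
        tokens = np.empty((0, 2 * n_markers), dtype=object)

    for j, (chrom, marker_id, pos_bp) in enumerate(map_rows):
        a = tokens[:, 2 * j]
        b = tokens[:, 2 * j + 1]
        a_missing = a == "0"
        b_missing = b == "0"
        half = a_missing ^ b_missing
        if half.any():
            i = int(np.flatnonzero(half)[0])
            raise PedMapFormatError(
                f"{ped_path}: individual {individuals[i].individual_id}, "
                f"marker {marker_id}: half-called genotype "
                f"'{a[i]} {b[i]}'"
            )
        called = ~a_missing
        observed = sorted(set(a[called]) | set(b[called]))
        if len(observed) > 2:
            raise PedMapFormatError(
                f"{ped_path}: marker {marker_id}: more than two alleles "
                f"observed: {observed}"
            )
        if len(observed) == 2:
            a1, a2 = observed  # lexicographic: a2 is the larger
        elif len(observed) == 1:
            a1, a2 = "0", observed[0]
        else:
            a1, a2 = "0", "0"
        markers.append(
            MarkerRecord(
                chrom=chrom,
                marker_id=marker_id,
                pos_bp=pos_bp,
                allele_a1=a1,
                allele_a2=a2,
            )
        )
        if n_ind and observed:
            dos = (a == a2).astype(np.int8) + (b == a2).astype(np.int8)
            calls[called, j] = dos[called]

    dataset = GenotypeDataset(individuals=individuals, markers=markers, calls=calls)
    return dataset.sorted_by_position()


def write_ped_map(
    dataset: GenotypeDataset,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    """Write a dataset as a PED/MAP pair that reads back equal (for markers
    with both alleles observed; see module docstring)."""
    with open(map_path, "w") as fh:
        for m in dataset.markers:
            fh.write(f"{m.chrom}\t{m.marker_id}\t0\t{m.pos_bp}\n")

    n_ind, n_markers = dataset.calls.shape
    # per-marker lookup from dosage (-1,0,1,2) to the allele-pair string
    cols = np.empty((n_ind, n_markers), dtype=object)
    for j, m in enumerate(dataset.markers):
        lut = np.array(
            [
                "0 0",
                f"{m.allele_a1} {m.allele_a1}",
                f"{m.allele_a1} {m.allele_a2}",
                f"{m.allele_a2} {m.allele_a2}",
            ],
            dtype=object,
        )
        cols[:, j] = lut[dataset.calls[:, j] + 1]

    with open(ped_path, "w") as fh:
        for i, ind in enumerate(dataset.individuals):
            prefix = f"{ind.breed}\t{ind.individual_id}\t0\t0\t0\t-9"
            if n_markers:
                fh.write(prefix + "\t" + "\t".join(cols[i]) + "\n")
            else:
                fh.write(prefix + "\n")
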