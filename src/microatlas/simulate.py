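"""Synthetic genomes, barcode groups, and contig read groups with truth.

The generator emulates the read structure of droplet single-microbe
shotgun sequencing: each "cell" is a barcode group of 1,000-10,000
paired 150 bp reads drawn from amplicons of 400-1,000 bp placed
uniformly on the host genome, with a per-barcode contamination fraction
drawn uniformly from [0, 0.49] and contaminant reads sampled from the
other community members. Pseudo-contigs model metagenomic assembly
output: a genome window plus an impurity fraction of foreign reads.
Every read carries a truth record so downstream classification,
clustering, and strain assignment can be scored exactly.

All randomness flows through numpy Generators keyed on explicit integer
seeds; identical seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import array_to_seq, seq_to_array
from .taxonomy import GenomeRecord, ReferenceSet, Taxonomy, TaxonomyNode

__all__ = [
    "SimulationConfig",
    "ReadTruth",
    "ReadPair",
    "BarcodeGroup",
    "generate_genome",
    "mutate_genome",
    "simulate_barcode_group",
    "iter_barcode_groups",
    "simulate_dataset",
    "simulate_contig_groups",
    "synthetic_community",
    "strain_panel_from_ancestor",
    "truth_table",
    "write_fastq_pair",
]


@dataclass(slots=True)
class SimulationConfig:
    """Knobs of the barcode-group generator.

    Defaults are the study conditions of the droplet assay being
    emulated: 150 bp paired ends from 400-1,000 bp amplicons, 1,000-10,000
    pairs per barcode, 0-49% contamination, 100 barcodes per species.
    """

    n_species: int = 10
    barcodes_per_species: int = 100
    read_length: int = 150
    amplicon_range: tuple[int, int] = (400, 1000)
    contamination_range: tuple[float, float] = (0.0, 0.49)
    reads_per_barcode_range: tuple[int, int] = (1000, 10000)
    substitution_error_rate: float = 0.0
    fixed_contamination: Optional[float] = None  # overrides the per-barcode draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.n_species <= 0 or self.barcodes_per_species <= 0:
            raise ValueError("counts and read length must be positive")
        lo, hi = self.amplicon_range
        if not (0 < lo <= hi):
            raise ValueError("amplicon_range must be ordered and positive")
        if lo < self.read_length:
            raise ValueError("minimum amplicon length must cover one read")
        c0, c1 = self.contamination_range
        if not (0.0 <= c0 <= c1 < 1.0):
            raise ValueError("contamination_range must satisfy 0 <= lo <= hi < 1")
        r0, r1 = self.reads_per_barcode_range
        if not (0 < r0 <= r1):
            raise ValueError("reads_per_barcode_range must be ordered and positive")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")


@dataclass(frozen=True, slots=True)
class ReadTruth:
    source_genome: str
    source_taxid: int
    start: int
    amplicon_len: int
    is_contaminant: bool


@dataclass(slots=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    truth: Optional[ReadTruth] = None


@dataclass(slots=True)
class BarcodeGroup:
    """All read pairs sharing one (corrected) cell barcode."""

    barcode_id: str
    read_pairs: list[ReadPair] = field(default_factory=list)
    batch: str = "single_cell"
    truth_host: Optional[str] = None
    truth_contamination: Optional[float] = None

    def __len__(self) -> int:
        return len(self.read_pairs)


# -- genome generation -----------------------------------------------------


def generate_genome(
    length: int,
    gc: float = 0.5,
    seed: int | Sequence[int] = 0,
    genome_id: str = "genome",
    taxid: int = 1,
) -> GenomeRecord:
    """Random i.i.d. genome with P(G) + P(C) = ``gc``; deterministic per seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p).astype(np.uint8)
    return GenomeRecord(genome_id, taxid, [array_to_seq(arr)])


def mutate_genome(
    genome: GenomeRecord,
    substitution_rate: float,
    seed: int | Sequence[int] = 0,
    genome_id: Optional[str] = None,
    taxid: Optional[int] = None,
) -> GenomeRecord:
    """Substitute each base independently (to a different base) at the given rate."""
    if not (0.0 <= substitution_rate < 1.0):
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out_seqs = []
    for seq in genome.sequences:
        arr = seq_to_array(seq).copy()
        hit = rng.random(arr.size) < substitution_rate
        n = int(hit.sum())
        if n:
            shifts = rng.integers(1, 4, size=n).astype(np.uint8)
            arr[hit] = (arr[hit] + shifts) % 4
        out_seqs.append(array_to_seq(arr))
    return GenomeRecord(
        genome_id or f"{genome.genome_id}_mut",
        taxid if taxid is not None else genome.taxid,
        out_seqs,
    )


# -- barcode groups --------------------------------------------------------


def _genome_array(genome: GenomeRecord) -> np.ndarray:
    # cache the 2-bit encoding on the record to avoid repeated conversion
    arr = getattr(genome, "_arr_cache", None)
    if arr is None or arr.size != genome.length:
        arr = np.concatenate([seq_to_array(s) for s in genome.sequences])
        try:
            object.__setattr__(genome, "_arr_cache", arr)
        except (AttributeError, TypeError):
            pass
    return arr


def _apply_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        arr = arr.copy()
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return arr


def _draw_pair(
    genome: GenomeRecord,
    arr: np.ndarray,
    read_len: int,
    amp_range: tuple[int, int],
    err: float,
    rng: np.random.Generator,
) -> tuple[str, str, int, int]:
    L = arr.size
    if L < amp_range[1]:
        raise ValueError(
            f"genome {genome.genome_id} ({L} bp) shorter than max amplicon "
            f"length {amp_range[1]}"
        )
    alen = int(rng.integers(amp_range[0], amp_range[1] + 1))
    start = int(rng.integers(0, L - alen + 1))
    amp = arr[start : start + alen]
    m1 = amp[:read_len]
    m2 = (3 - amp[alen - read_len :])[::-1]  # reverse complement of the 3' end
    if err > 0:
        m1 = _apply_errors(m1, err, rng)
        m2 = _apply_errors(m2, err, rng)
    return array_to_seq(m1), array_to_seq(m2), start, alen


def _quality_string(length: int, error_rate: float) -> str:
    if error_rate <= 0:
        return "F" * length  # Q37
    q = min(40, max(2, round(-10 * np.log10(error_rate))))
    return chr(33 + q) * length


def simulate_barcode_group(
    refset: ReferenceSet,
    host: str,
    config: SimulationConfig,
    seed: int | Sequence[int] = 0,
    barcode_id: Optional[str] = None,
    n_pairs: Optional[int] = None,
    contamination: Optional[float] = None,
) -> BarcodeGroup:
    """Simulate one barcode group from ``host`` plus contaminant reads.

    ``n_pairs`` and ``contamination`` override the random draws (useful
    for constructing exact fixtures); the contaminant pair count is
    round-half-to-even of ``n_pairs * contamination``.
    """
    if host not in refset.genomes:
        raise KeyError(f"host genome {host!r} not in reference set")
    rng = np.random.default_rng(seed)
    bc = barcode_id or host
    r0, r1 = config.reads_per_barcode_range
    if n_pairs is None:
        n_pairs = int(rng.integers(r0, r1 + 1))
    if contamination is None:
        if config.fixed_contamination is not None:
            contamination = config.fixed_contamination
        else:
            c0, c1 = config.contamination_range
            contamination = float(rng.uniform(c0, c1))
    n_contam = round(n_pairs * contamination)
    others = sorted(g for g in refset.genomes if g != host)
    if n_contam > 0 and not others:
        raise ValueError("contamination requested but reference set has one genome")

    host_rec = refset[host]
    host_arr = _genome_array(host_rec)
    if host_arr.size < config.amplicon_range[1]:
        raise ValueError(
            f"host genome {host} shorter than max amplicon length "
            f"{config.amplicon_range[1]}"
        )
    err = config.substitution_error_rate
    qual = _quality_string(config.read_length, err)

    pairs: list[ReadPair] = []
    for i in range(n_pairs - n_contam):
        s1, s2, start, alen = _draw_pair(
            host_rec, host_arr, config.read_length, config.amplicon_range, err, rng
        )
        pairs.append(
            ReadPair(
                f"{bc}:{i}",
                s1,
                qual,
                s2,
                qual,
                ReadTruth(host, host_rec.taxid, start, alen, False),
            )
        )
    for j in range(n_contam):
        src = others[int(rng.integers(0, len(others)))]
        rec = refset[src]
        s1, s2, start, alen = _draw_pair(
            rec, _genome_array(rec), config.read_length, config.amplicon_range, err, rng
        )
        pairs.append(
            ReadPair(
                f"{bc}:{n_pairs - n_contam + j}",
                s1,
                qual,
                s2,
                qual,
                ReadTruth(src, rec.taxid, start, alen, True),
            )
        )
    return BarcodeGroup(
        barcode_id=bc,
        read_pairs=pairs,
        batch="single_cell",
        truth_host=host,
        truth_contamination=n_contam / n_pairs,
    )


def iter_barcode_groups(
    refset: ReferenceSet,
    config: SimulationConfig,
    seed: Optional[int] = None,
    barcode_sequences: Optional[Sequence[str]] = None,
) -> Iterator[BarcodeGroup]:
    """Yield ``barcodes_per_species`` groups for each of the first
    ``n_species`` genomes (sorted by id), deterministically per seed.

    When ``barcode_sequences`` is given, barcode ids are taken from it in
    order (so raw reads can embed a whitelist barcode); otherwise ids are
    ``BC<serial>``.
    """
    if seed is None:
        seed = config.seed
    hosts = sorted(refset.genomes)[: config.n_species]
    if len(hosts) < config.n_species:
        raise ValueError(
            f"reference set has {len(refset)} genomes, need {config.n_species}"
        )
    total = config.n_species * config.barcodes_per_species
    if barcode_sequences is not None and len(barcode_sequences) < total:
        raise ValueError("not enough barcode sequences for the configured groups")
    serial = 0
    for host in hosts:
        for _ in range(config.barcodes_per_species):
            bc = (
                barcode_sequences[serial]
                if barcode_sequences is not None
                else f"BC{serial:06d}"
            )
            yield simulate_barcode_group(
                refset, host, config, seed=(seed, serial), barcode_id=bc
            )
            serial += 1


def truth_table(groups: Iterable[BarcodeGroup]) -> pd.DataFrame:
    """One row per read pair: barcode, source genome/taxid, placement, flag."""
    rows = {
        "read_id": [],
        "barcode_id": [],
        "source_genome": [],
        "source_taxid": [],
        "start": [],
        "amplicon_len": [],
        "is_contaminant": [],
    }
    for g in groups:
        for rp in g.read_pairs:
            t = rp.truth
            rows["read_id"].append(rp.read_id)
            rows["barcode_id"].append(g.barcode_id)
            rows["source_genome"].append(t.source_genome if t else "")
            rows["source_taxid"].append(t.source_taxid if t else -1)
            rows["start"].append(t.start if t else -1)
            rows["amplicon_len"].append(t.amplicon_len if t else -1)
            rows["is_contaminant"].append(bool(t.is_contaminant) if t else False)
    return pd.DataFrame(rows)


def write_fastq_pair(
    groups: Iterable[BarcodeGroup],
    r1_path: str | Path,
    r2_path: str | Path,
    embed_barcode: bool = False,
) -> int:
    """Write groups as a paired FASTQ; returns the number of pairs written.

    With ``embed_barcode`` the barcode id (assumed to be a DNA sequence)
    is prepended to read 1, mimicking raw instrument output.
    """
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for g in groups:
            for rp in g.read_pairs:
                s1 = (g.barcode_id + rp.seq1) if embed_barcode else rp.seq1
                q1 = ("I" * len(g.barcode_id) + rp.qual1) if embed_barcode else rp.qual1
                f1.write(f"@{rp.read_id}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rp.read_id}/2\n{rp.seq2}\n+\n{rp.qual2}\n")
                n += 1
    return n


def simulate_dataset(
    refset: ReferenceSet,
    config: SimulationConfig,
    out_dir: str | Path,
    seed: Optional[int] = None,
    barcode_sequences: Optional[Sequence[str]] = None,
    embed_barcode: bool = False,
) -> dict[str, Path]:
    """Simulate the full dataset and write FASTQ pair + truth TSV.

    Returns the paths written (keys ``r1``, ``r2``, ``truth``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r1, r2 = out / "reads_R1.fastq", out / "reads_R2.fastq"
    groups = list(iter_barcode_groups(refset, config, seed, barcode_sequences))
    write_fastq_pair(groups, r1, r2, embed_barcode=embed_barcode)
    truth = truth_table(groups)
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"r1": r1, "r2": r2, "truth": truth_path}


# -- pseudo-contigs --------------------------------------------------------


def simulate_contig_groups(
    refset: ReferenceSet,
    n_contigs: int,
    contig_length_range: tuple[int, int] = (5000, 20000),
    reads_per_contig_range: tuple[int, int] = (1000, 5000),
    impurity_range: tuple[float, float] = (0.0, 0.2),
    seed: int = 0,
    read_length: int = 150,
    amplicon_range: tuple[int, int] = (400, 1000),
) -> list[BarcodeGroup]:
    """Read groups of pseudo-contigs (genome windows) tagged ``batch="contig"``.

    Each contig's reads come from its window plus an impurity fraction of
    reads from other genomes, modelling chimeric or cross-mapped contigs.
    """
    c0, c1 = contig_length_range
    if not (0 < c0 <= c1):
        raise ValueError("contig_length_range must be ordered and positive")
    if c0 < amplicon_range[1]:
        raise ValueError("contig min length must cover the max amplicon")
    rng = np.random.default_rng(seed)
    ids = sorted(refset.genomes)
    groups: list[BarcodeGroup] = []
    for c in range(n_contigs):
        src = ids[int(rng.integers(0, len(ids)))]
        rec = refset[src]
        arr = _genome_array(rec)
        clen = int(rng.integers(c0, min(c1, arr.size) + 1))
        if clen > arr.size:
            raise ValueError(f"contig window exceeds genome {src} length")
        wstart = int(rng.integers(0, arr.size - clen + 1))
        window = GenomeRecord(f"{src}:ctg{c}", rec.taxid, [array_to_seq(arr[wstart : wstart + clen])])
        n_reads = int(rng.integers(reads_per_contig_range[0], reads_per_contig_range[1] + 1))
        impurity = float(rng.uniform(impurity_range[0], impurity_range[1]))
        n_foreign = round(n_reads * impurity)
        warr = _genome_array(window)
        others = [g for g in ids if g != src]
        pairs: list[ReadPair] = []
        qual = _quality_string(read_length, 0.0)
        bc = f"CTG{c:05d}"
        for i in range(n_reads - n_foreign):
            s1, s2, start, alen = _draw_pair(window, warr, read_length, amplicon_range, 0.0, rng)
            pairs.append(
                ReadPair(
                    f"{bc}:{i}",
                    s1,
                    qual,
                    s2,
                    qual,
                    ReadTruth(src, rec.taxid, wstart + start, alen, False),
                )
            )
        for j in range(n_foreign):
            osrc = others[int(rng.integers(0, len(others)))]
            orec = refset[osrc]
            s1, s2, start, alen = _draw_pair(
                orec, _genome_array(orec), read_length, amplicon_range, 0.0, rng
            )
            pairs.append(
                ReadPair(
                    f"{bc}:{n_reads - n_foreign + j}",
                    s1,
                    qual,
                    s2,
                    qual,
                    ReadTruth(osrc, orec.taxid, start, alen, True),
                )
            )
        groups.append(
            BarcodeGroup(
                barcode_id=bc,
                read_pairs=pairs,
                batch="contig",
                truth_host=src,
                truth_contamination=n_foreign / n_reads,
            )
        )
    return groups


# -- community builders ----------------------------------------------------


def synthetic_community(
    n_genera: int = 10,
    species_per_genus: int = 1,
    genome_length: int = 50_000,
    gc: float = 0.5,
    seed: int = 0,
    species_divergence: float = 0.05,
) -> ReferenceSet:
    """A toy community with its taxonomy: one random ancestor genome per
    genus; extra species within a genus are substitution mutants of it.

    Taxids: root=1, superkingdom=2, genus ``100+i``, species
    ``10000 + 100*i + j``. Genome ids are ``g<i>_s<j>``.
    """
    nodes = [
        TaxonomyNode(1, 1, "root", "root"),
        TaxonomyNode(2, 1, "superkingdom", "Bacteria"),
    ]
    genomes: list[GenomeRecord] = []
    for i in range(n_genera):
        gtax = 100 + i
        nodes.append(TaxonomyNode(gtax, 2, "genus", f"Genus{i:02d}"))
        ancestor = generate_genome(genome_length, gc, seed=(seed, i), genome_id=f"g{i:02d}_s00")
        for j in range(species_per_genus):
            stax = 10000 + 100 * i + j
            nodes.append(TaxonomyNode(stax, gtax, "species", f"Genus{i:02d} sp{j:02d}"))
            if j == 0:
                genomes.append(GenomeRecord(f"g{i:02d}_s00", stax, ancestor.sequences))
            else:
                mut = mutate_genome(
                    ancestor,
                    species_divergence,
                    seed=(seed, i, j),
                    genome_id=f"g{i:02d}_s{j:02d}",
                    taxid=stax,
                )
                genomes.append(mut)
    return ReferenceSet(genomes, Taxonomy(nodes))


def strain_panel_from_ancestor(
    n_strains: int = 4,
    genome_length: int = 20_000,
    divergence: float = 0.01,
    gc: float = 0.5,
    seed: int = 0,
) -> list[GenomeRecord]:
    """Strain genomes derived from one random ancestor at the given
    per-base substitution rate (pairwise identity ~ (1 - divergence)^2)."""
    ancestor = generate_genome(genome_length, gc, seed=(seed, 987654321))
    panel = []
    for s in range(n_strains):
        panel.append(
            mutate_genome(
                ancestor, divergence, seed=(seed, s), genome_id=f"strain{s:02d}", taxid=1
            )
        )
    return panel
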