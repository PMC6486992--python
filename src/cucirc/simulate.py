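"""Synthetic genomes, gene models and truth-labelled junction tables.

The generator builds everything the pipeline consumes, constructively, so
every derived label is exact by construction: multi-exon gene models on a
few chromosomes plus unanchored scaffolds; a circRNA population placed at
exon boundaries, inside single introns, or in intergenic gaps according to a
configurable origin mix; boundary dinucleotides overwritten with the drawn
splice-signal pair; a flagged subset with planted inverted-repeat flanks;
MITE intervals on both flanks of a flagged subset; and negative-binomial
junction counts across tissues x conditions x replicates with salt-induced
fold changes on a flagged differential subset.  Background sequence is
i.i.d. uniform over ACGT, so repeats exist only where planted and
flank-search truth is unambiguous.

Default proportions mirror a real cucumber salt-stress cohort: origin mix
79.5 / 4.9 / 15.6 percent (exonic / intronic / intergenic), 11.7 percent
canonical GT/AG (or CT/AC) signals, and a baseline of about 20 junction
reads per circRNA per library, between the junction-read depth observed per
detected circ in leaf (~12) and root (~32) libraries.
Discrete subset sizes (origins, canonical signals, planted flanks, MITEs,
differential circs) are allocated deterministically by largest-remainder
rounding of the configured fractions; stochasticity enters through
placement, sequence and counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io_formats import (
    CircRecord,
    GeneModel,
    SampleStats,
    make_circ_id,
    reverse_complement,
    write_genome_fasta,
    write_gff3,
    write_junction_table,
    write_mite_bed,
    write_sample_stats,
)
from .enrich import write_gene_terms

__all__ = ["SimConfig", "SimResult", "simulate", "make_fixture", "FIXTURE_NAMES"]

_TYPE_LABEL = {"exonic": "exon", "intronic": "intron", "intergenic": "intergenic_region"}


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chromosomes: int = 3
    chromosome_length: int = 700_000
    n_scaffolds: int = 3
    scaffold_length: int = 20_000
    # genes
    n_genes: int = 150
    exons_per_gene: Tuple[int, int] = (3, 7)
    exon_length: Tuple[int, int] = (80, 400)
    intron_length: Tuple[int, int] = (120, 900)
    intergenic_gap: Tuple[int, int] = (1500, 4000)
    # circRNAs
    n_circs: int = 600
    origin_mix: Tuple[float, float, float] = (0.795, 0.049, 0.156)  # exonic, intronic, intergenic
    intergenic_span: Tuple[int, int] = (200, 1200)
    canonical_signal_fraction: float = 0.117
    planted_flank_fraction: float = 0.03
    flank_repeat_length: int = 24
    flank_window: int = 1000
    mite_fraction: float = 0.02
    mite_length: int = 150
    # expression
    tissues: Tuple[str, ...] = ("L", "R")
    conditions: Tuple[str, ...] = ("CK", "Na")
    n_replicates: int = 2
    nb_mean: float = 20.0
    nb_mean_sigma: float = 0.5  # lognormal spread of per-circ baseline means
    nb_dispersion: float = 0.2
    tissue_specific_fraction: float = 0.3
    de_fraction: float = 0.2
    de_fold: float = 4.0
    read_length: int = 150
    library_size_mean: float = 5e7
    library_size_sigma: float = 0.1
    gene_abundance_noise_sigma: float = 0.6
    # miRNA / mRNA
    n_mirnas: int = 10
    mirna_length: int = 21
    n_planted_circ_sites: int = 6
    n_mrnas: int = 20
    mrna_length: int = 500
    # annotation terms
    n_terms: int = 15

    def sample_ids(self) -> List[str]:
        return [
            f"{cond}-{tissue}{rep}"
            for tissue in self.tissues
            for cond in self.conditions
            for rep in range(1, self.n_replicates + 1)
        ]


@dataclass
class SimResult:
    config: SimConfig
    genome: Dict[str, str]
    genes: List[GeneModel]
    circs: List[CircRecord]  # template records (no counts)
    tables: Dict[str, List[CircRecord]]  # per-sample junction tables
    stats: List[SampleStats]
    mites: Dict[str, List[Tuple[int, int]]]
    gene_abundance: pd.DataFrame  # genes x samples
    mirnas: Dict[str, str]
    mrnas: Dict[str, str]
    gene_terms: Dict[str, Set[str]]
    truth: pd.DataFrame  # indexed by circ_id
    planted_mrna_targets: pd.DataFrame  # mirna, mrna_id

    @property
    def parent_map(self) -> Dict[str, str]:
        t = self.truth
        return {
            cid: t.loc[cid, "parent_gene"]
            for cid in t.index
            if isinstance(t.loc[cid, "parent_gene"], str)
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome_fasta(self.genome, out / "genome.fa")
        write_gff3(self.genes, out / "genes.gff3")
        write_mite_bed(self.mites, out / "mites.bed")
        write_sample_stats(self.stats, out / "sample_stats.tsv")
        (out / "junctions").mkdir(exist_ok=True)
        for sample in self.config.sample_ids():
            write_junction_table(
                self.tables[sample], out / "junctions" / f"{sample}.tsv"
            )
        self.gene_abundance.to_csv(
            out / "gene_abundance.tsv", sep="\t", index_label="gene_id",
            float_format="%.6g",
        )
        _write_fasta(self.mirnas, out / "mirnas.fa")
        _write_fasta(self.mrnas, out / "mrnas.fa")
        write_gene_terms(self.gene_terms, out / "gene_terms.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index_label="circ_id")
        self.planted_mrna_targets.to_csv(
            out / "planted_mrna_targets.tsv", sep="\t", index=False
        )
        with open(out / "simconfig.txt", "w") as fh:
            for key, value in asdict(self.config).items():
                fh.write(f"{key} = {value}\n")


def _write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def _largest_remainder(total: int, fractions: Sequence[float]) -> List[int]:
    raw = [total * f for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


class SimError(ValueError):
    pass


def simulate(config: SimConfig) -> SimResult:
    """Generate a complete, fully reproducible synthetic dataset."""
    rng = np.random.default_rng(config.seed)
    margin = config.flank_window + 500

    # --- genome skeleton -------------------------------------------------
    arrays: Dict[str, np.ndarray] = {}
    for i in range(1, config.n_chromosomes + 1):
        arrays[f"Chr{i}"] = _random_seq(rng, config.chromosome_length)
    for i in range(1, config.n_scaffolds + 1):
        arrays[f"scaffold{i:04d}"] = _random_seq(rng, config.scaffold_length)
    chrom_names = [f"Chr{i}" for i in range(1, config.n_chromosomes + 1)]
    scaffold_names = [f"scaffold{i:04d}" for i in range(1, config.n_scaffolds + 1)]

    # --- gene placement ---------------------------------------------------
    genes: List[GeneModel] = []
    gaps: List[Tuple[str, int, int]] = []  # intergenic gaps usable for circs
    per_chrom = _largest_remainder(
        config.n_genes, [1.0 / config.n_chromosomes] * config.n_chromosomes
    )
    gi = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        cursor = margin
        placed = 0
        while placed < n_here:
            gap = int(rng.integers(*config.intergenic_gap))
            start = cursor + gap
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_lens = rng.integers(*config.exon_length, size=n_ex)
            intron_lens = rng.integers(*config.intron_length, size=max(n_ex - 1, 0))
            exons = []
            pos = start
            for j in range(n_ex):
                exons.append((pos, pos + int(exon_lens[j]) - 1))
                pos = exons[-1][1] + 1
                if j < n_ex - 1:
                    pos += int(intron_lens[j])
            gene_end = exons[-1][1]
            if gene_end > config.chromosome_length - margin:
                break
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel.from_genomic_exons(f"CsaSim{gi:04d}", chrom, strand, exons)
            )
            gaps.append((chrom, cursor + 1, start - 1))
            cursor = gene_end
            placed += 1
        if placed < n_here:
            raise SimError(
                f"could not place {n_here} genes on {chrom}: increase "
                "chromosome_length or reduce n_genes/exon sizes"
            )
    for name in scaffold_names:
        lo = min(config.flank_window, config.scaffold_length // 4)
        gaps.append((name, lo + 1, config.scaffold_length - lo))

    # --- circRNA placement ------------------------------------------------
    n_exonic, n_intronic, n_intergenic = _largest_remainder(
        config.n_circs, list(config.origin_mix)
    )
    used_keys: Set[Tuple[str, int, int]] = set()
    reserved: Set[Tuple[str, int]] = set()  # splice-signal dinucleotide slots

    def reserve(circ_key: Tuple[str, int, int]) -> bool:
        chrom, start, end = circ_key
        slots = [
            (chrom, start - 2), (chrom, start - 1),
            (chrom, end + 1), (chrom, end + 2),
        ]
        if any(s in reserved for s in slots):
            return False
        reserved.update(slots)
        return True

    circ_rows: List[dict] = []

    multi_exon_genes = [g for g in genes if len(g.exons) >= 2]
    attempts = 0
    max_attempts = 400 * config.n_circs
    placed_exonic = 0
    while placed_exonic < n_exonic:
        attempts += 1
        if attempts > max_attempts:
            raise SimError(
                "could not place all exonic circRNAs: increase n_genes or "
                "exons_per_gene (more distinct exon-boundary pairs needed)"
            )
        g = genes[int(rng.integers(len(genes)))]
        ex = g.exons_genomic
        i = int(rng.integers(len(ex)))
        j = int(rng.integers(i, len(ex)))
        start, end = ex[i][0], ex[j][1]
        key = (g.chrom, start, end)
        if key in used_keys or not reserve(key):
            continue
        used_keys.add(key)
        circ_rows.append(
            {"chrom": g.chrom, "start": start, "end": end, "origin": "exonic",
             "parent_gene": g.gene_id, "strand": g.strand}
        )
        placed_exonic += 1

    placed_intronic = 0
    while placed_intronic < n_intronic:
        attempts += 1
        if attempts > max_attempts:
            raise SimError(
                "could not place all intronic circRNAs: increase intron_length"
            )
        g = multi_exon_genes[int(rng.integers(len(multi_exon_genes)))]
        introns = [iv for iv in g.introns_genomic if iv[1] - iv[0] + 1 >= 60]
        if not introns:
            continue
        s, e = introns[int(rng.integers(len(introns)))]
        length = int(rng.integers(40, e - s + 1))
        start = int(rng.integers(s, e - length + 2))
        end = start + length - 1
        key = (g.chrom, start, end)
        if key in used_keys or not reserve(key):
            continue
        used_keys.add(key)
        circ_rows.append(
            {"chrom": g.chrom, "start": start, "end": end, "origin": "intronic",
             "parent_gene": g.gene_id, "strand": g.strand}
        )
        placed_intronic += 1

    usable_gaps = [
        (chrom, lo, hi)
        for chrom, lo, hi in gaps
        if hi - lo + 1 >= config.intergenic_span[0] + 60
    ]
    placed_intergenic = 0
    while placed_intergenic < n_intergenic:
        attempts += 1
        if attempts > max_attempts:
            raise SimError(
                "could not place all intergenic circRNAs: increase "
                "intergenic_gap or chromosome_length"
            )
        chrom, lo, hi = usable_gaps[int(rng.integers(len(usable_gaps)))]
        width = hi - lo + 1
        span = int(
            rng.integers(
                config.intergenic_span[0],
                min(config.intergenic_span[1], width - 50) + 1,
            )
        )
        start = int(rng.integers(lo + 20, hi - span - 20 + 2))
        end = start + span - 1
        key = (chrom, start, end)
        if key in used_keys or not reserve(key):
            continue
        used_keys.add(key)
        circ_rows.append(
            {"chrom": chrom, "start": start, "end": end, "origin": "intergenic",
             "parent_gene": None, "strand": "unknown"}
        )
        placed_intergenic += 1

    truth = pd.DataFrame(circ_rows)
    truth["circ_id"] = [
        make_circ_id(r["chrom"], r["start"], r["end"]) for r in circ_rows
    ]
    truth = truth.set_index("circ_id")
    order = np.argsort(
        truth[["chrom", "start", "end"]].apply(tuple, axis=1).to_numpy()
    )
    truth = truth.iloc[order]
    n = len(truth)

    # --- splice signals ---------------------------------------------------
    n_canonical = _largest_remainder(
        n, [config.canonical_signal_fraction, 1 - config.canonical_signal_fraction]
    )[0]
    canon_flags = np.zeros(n, dtype=bool)
    canon_flags[rng.permutation(n)[:n_canonical]] = True
    donors, acceptors = [], []
    bases = "ACGT"
    for flag in canon_flags:
        if flag:
            donor, acceptor = ("GT", "AG") if rng.random() < 0.5 else ("CT", "AC")
        else:
            while True:
                donor = bases[rng.integers(4)] + bases[rng.integers(4)]
                acceptor = bases[rng.integers(4)] + bases[rng.integers(4)]
                if (donor, acceptor) not in {("GT", "AG"), ("CT", "AC")}:
                    break
        donors.append(donor)
        acceptors.append(acceptor)
    truth["donor"] = donors
    truth["acceptor"] = acceptors
    truth["canonical"] = canon_flags

    code = {b: k for k, b in enumerate(bases)}
    for cid, row in truth.iterrows():
        arr = arrays[row["chrom"]]
        s, e = row["start"], row["end"]
        arr[s - 3] = code[row["acceptor"][0]]
        arr[s - 2] = code[row["acceptor"][1]]
        arr[e] = code[row["donor"][0]]
        arr[e + 1] = code[row["donor"][1]]

    # --- planted inverted-repeat flanks ------------------------------------
    n_flank = _largest_remainder(
        n, [config.planted_flank_fraction, 1 - config.planted_flank_fraction]
    )[0]
    window, rep_len = config.flank_window, config.flank_repeat_length
    chrom_circs = truth[truth["chrom"].isin(chrom_names)]
    win_of = {
        cid: (
            (row["start"] - window, row["start"] - 1),
            (row["end"] + 1, row["end"] + window),
        )
        for cid, row in truth.iterrows()
    }

    def interval_ov(a: Tuple[int, int], b: Tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)

    planted_flags: Dict[str, bool] = {cid: False for cid in truth.index}
    occupied: List[Tuple[str, int, int]] = []  # planted repeat intervals

    def free(chrom: str, s: int, e: int) -> bool:
        if any(co == chrom and interval_ov((s, e), (a, b)) for co, a, b in occupied):
            return False
        return not any((chrom, p) in reserved for p in range(s, e + 1))

    candidates = list(chrom_circs.index)
    rng.shuffle(candidates)
    for cid in candidates:
        if sum(planted_flags.values()) >= n_flank:
            break
        row = truth.loc[cid]
        chrom = row["chrom"]
        (u0, u1), (d0, d1) = win_of[cid]
        if u0 < 1 or d1 > len(arrays[chrom]):
            continue
        ok_placement = None
        for _ in range(30):
            us = int(rng.integers(u0, u1 - rep_len + 2))
            ds = int(rng.integers(d0, d1 - rep_len + 2))
            up_iv, down_iv = (us, us + rep_len - 1), (ds, ds + rep_len - 1)
            if not (free(chrom, *up_iv) and free(chrom, *down_iv)):
                continue
            # leakage check: the pair must not be jointly visible from any
            # other circ's window pair (minimum detectable overlap 12 bp)
            leak = False
            for other, ((ou0, ou1), (od0, od1)) in win_of.items():
                if other == cid or truth.loc[other, "chrom"] != chrom:
                    continue
                o_up, o_down = (ou0, ou1), (od0, od1)
                if (
                    min(interval_ov(up_iv, o_up), interval_ov(down_iv, o_down)) >= 12
                    or min(interval_ov(down_iv, o_up), interval_ov(up_iv, o_down)) >= 12
                ):
                    leak = True
                    break
            if not leak:
                ok_placement = (us, ds)
                break
        if ok_placement is None:
            continue
        us, ds = ok_placement
        repeat = _random_seq(rng, rep_len)
        arr = arrays[chrom]
        arr[us - 1 : us + rep_len - 1] = repeat
        # reverse complement: complement codes are 3 - code
        arr[ds - 1 : ds + rep_len - 1] = (3 - repeat)[::-1]
        occupied.append((chrom, us, us + rep_len - 1))
        occupied.append((chrom, ds, ds + rep_len - 1))
        planted_flags[cid] = True
    if sum(planted_flags.values()) < n_flank:
        raise SimError(
            "could not plant all inverted-repeat flanks without cross-talk: "
            "increase chromosome_length or intergenic_gap"
        )
    truth["planted_flank"] = [planted_flags[c] for c in truth.index]

    # --- expression design (before miRNA sites so DE circs are known) ------
    de_up, de_down, _ = _largest_remainder(
        n, [config.de_fraction / 2, config.de_fraction / 2, 1 - config.de_fraction]
    )
    perm = rng.permutation(n)
    de_status = np.array(["none"] * n, dtype=object)
    de_status[perm[:de_up]] = "up"
    de_status[perm[de_up : de_up + de_down]] = "down"
    truth["de_status"] = de_status
    truth["true_fold"] = np.where(
        de_status == "up", config.de_fold,
        np.where(de_status == "down", 1.0 / config.de_fold, 1.0),
    )

    profiles = []
    factors = {t: np.ones(n) for t in config.tissues}
    for i in range(n):
        if len(config.tissues) > 1 and rng.random() < config.tissue_specific_fraction:
            specific = config.tissues[int(rng.integers(len(config.tissues)))]
            profiles.append(specific)
            for t in config.tissues:
                factors[t][i] = 1.0 if t == specific else 0.02
        else:
            profiles.append("shared")
    truth["tissue_profile"] = profiles
    for t in config.tissues:
        truth[f"factor_{t}"] = factors[t]

    # --- planted miRNA sites ------------------------------------------------
    mirnas = {
        f"csa-miR-sim{i:02d}": _to_str(_random_seq(rng, config.mirna_length))
        for i in range(1, config.n_mirnas + 1)
    }
    mirna_ids = list(mirnas)
    planted_mirna: Dict[str, str] = {}
    de_exonic = [
        cid
        for cid in truth.index
        if truth.loc[cid, "de_status"] != "none" and truth.loc[cid, "origin"] == "exonic"
    ]
    rng.shuffle(de_exonic)
    site_len = config.mirna_length
    for k, cid in enumerate(de_exonic):
        if len(planted_mirna) >= min(config.n_planted_circ_sites, len(mirna_ids)):
            break
        row = truth.loc[cid]
        gene = next(g for g in genes if g.gene_id == row["parent_gene"])
        segs = [
            (max(s, row["start"]), min(e, row["end"]))
            for s, e in gene.exons_genomic
            if max(s, row["start"]) <= min(e, row["end"])
        ]
        segs = [(s, e) for s, e in segs if e - s + 1 >= site_len + 8]
        if not segs:
            continue
        s, e = segs[int(rng.integers(len(segs)))]
        pos = int(rng.integers(s + 3, e - site_len - 2))
        if not free(row["chrom"], pos, pos + site_len - 1):
            continue
        mid = mirna_ids[len(planted_mirna)]
        m_arr = np.array([code[b] for b in mirnas[mid]], dtype=np.int8)
        arrays[row["chrom"]][pos - 1 : pos + site_len - 1] = (3 - m_arr)[::-1]
        occupied.append((row["chrom"], pos, pos + site_len - 1))
        planted_mirna[cid] = mid
    truth["planted_mirna"] = [planted_mirna.get(c, "") for c in truth.index]

    # --- mRNAs with planted sites -------------------------------------------
    mrnas: Dict[str, str] = {}
    planted_rows = []
    mrna_arrays = {
        f"mRNA{i:03d}": _random_seq(rng, config.mrna_length)
        for i in range(1, config.n_mrnas + 1)
    }
    target_mirnas = mirna_ids[: max(1, config.n_mirnas // 2)]
    mrna_names = list(mrna_arrays)
    for k, mid in enumerate(target_mirnas):
        m_arr = np.array([code[b] for b in mirnas[mid]], dtype=np.int8)
        for copy in range(2):
            name = mrna_names[(2 * k + copy) % len(mrna_names)]
            pos = int(rng.integers(10, config.mrna_length - site_len - 10))
            mrna_arrays[name][pos : pos + site_len] = (3 - m_arr)[::-1]
            planted_rows.append({"mirna": mid, "mrna_id": name})
    mrnas = {name: _to_str(arr) for name, arr in mrna_arrays.items()}
    planted_mrna_targets = pd.DataFrame(
        planted_rows, columns=["mirna", "mrna_id"]
    ).drop_duplicates()

    # --- MITE intervals ------------------------------------------------------
    n_mite = _largest_remainder(
        n, [config.mite_fraction, 1 - config.mite_fraction]
    )[0]
    mites: Dict[str, List[Tuple[int, int]]] = {}
    mite_flags = {cid: False for cid in truth.index}
    cands = [c for c in chrom_circs.index if not planted_flags[c]]
    rng.shuffle(cands)
    for cid in cands[:n_mite]:
        row = truth.loc[cid]
        (u0, u1), (d0, d1) = win_of[cid]
        lu = int(rng.integers(u0, u1 - config.mite_length + 2))
        ld = int(rng.integers(d0, d1 - config.mite_length + 2))
        mites.setdefault(row["chrom"], []).append((lu, lu + config.mite_length - 1))
        mites.setdefault(row["chrom"], []).append((ld, ld + config.mite_length - 1))
        mite_flags[cid] = True
    # decoys overlapping only one window
    for cid in cands[n_mite : n_mite + max(2, n_mite)]:
        row = truth.loc[cid]
        (u0, u1), _ = win_of[cid]
        lu = int(rng.integers(u0, u1 - config.mite_length + 2))
        mites.setdefault(row["chrom"], []).append((lu, lu + config.mite_length - 1))
    # truth flag: both flank windows overlap >= 1 MITE interval
    for cid in truth.index:
        row = truth.loc[cid]
        ivals = mites.get(row["chrom"], [])
        (u0, u1), (d0, d1) = win_of[cid]
        up = any(interval_ov((u0, u1), iv) for iv in ivals)
        down = any(interval_ov((d0, d1), iv) for iv in ivals)
        mite_flags[cid] = up and down
    truth["mite_both"] = [mite_flags[c] for c in truth.index]
    for v in mites.values():
        v.sort()

    # --- library stats and counts --------------------------------------------
    samples = config.sample_ids()
    stats: List[SampleStats] = []
    for sid in samples:
        mapped = int(
            rng.lognormal(np.log(config.library_size_mean), config.library_size_sigma)
        )
        total = int(mapped / rng.uniform(0.6, 0.95))
        stats.append(SampleStats(sid, total, mapped, config.read_length))
    mapped_by = {s.sample_id: s.mapped_reads for s in stats}

    base = rng.lognormal(np.log(config.nb_mean), config.nb_mean_sigma, size=n)
    counts = pd.DataFrame(0, index=truth.index, columns=samples, dtype=np.int64)
    for sid in samples:
        cond, rest = sid.split("-", 1)
        tissue = rest[:-1] if rest[:-1] in config.tissues else rest[0]
        cond_fold = np.where(
            (truth["de_status"] == "up") & (cond == config.conditions[-1]),
            config.de_fold,
            np.where(
                (truth["de_status"] == "down") & (cond == config.conditions[-1]),
                1.0 / config.de_fold,
                1.0,
            ),
        )
        mu = (
            base
            * truth[f"factor_{tissue}"].to_numpy()
            * cond_fold
            * (mapped_by[sid] / config.library_size_mean)
        )
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            counts[sid] = rng.negative_binomial(r, p)
        else:
            counts[sid] = rng.poisson(mu)

    circs = [
        CircRecord(
            row["chrom"], int(row["start"]), int(row["end"]),
            row["strand"], 0, _TYPE_LABEL[row["origin"]],
            row["parent_gene"] if isinstance(row["parent_gene"], str) else None,
        )
        for cid, row in truth.iterrows()
    ]
    tables: Dict[str, List[CircRecord]] = {}
    for sid in samples:
        recs = []
        for c, cid in zip(circs, truth.index):
            k = int(counts.loc[cid, sid])
            if k > 0:
                recs.append(
                    CircRecord(
                        c.chrom, c.start, c.end, c.strand, k,
                        c.reported_type, c.gene_id,
                    )
                )
        tables[sid] = recs

    # --- fabricated parental-gene abundance ------------------------------------
    genome = {name: _to_str(arrays[name]) for name in arrays}
    srpbm_factor = {
        s.sample_id: 1e9 / (s.mapped_reads * s.read_length) for s in stats
    }
    circ_srpbm = counts.astype(float)
    for sid in samples:
        circ_srpbm[sid] = circ_srpbm[sid] * srpbm_factor[sid]
    gene_noise = {
        g.gene_id: rng.lognormal(0.0, config.gene_abundance_noise_sigma)
        for g in genes
    }
    gene_rows = {}
    for g in genes:
        member_ids = [cid for cid in truth.index if truth.loc[cid, "parent_gene"] == g.gene_id]
        if member_ids:
            profile = circ_srpbm.loc[member_ids].sum(axis=0) + 0.5
        else:
            profile = pd.Series(rng.lognormal(np.log(10.0), 0.5), index=samples)
        gene_rows[g.gene_id] = profile * gene_noise[g.gene_id]
    gene_abundance = pd.DataFrame(gene_rows).T
    gene_abundance.columns = samples

    # --- annotation terms --------------------------------------------------------
    terms = [f"T{i:03d}" for i in range(1, config.n_terms + 1)]
    gene_terms: Dict[str, Set[str]] = {}
    for g in genes:
        k = int(rng.integers(1, 4))
        gene_terms[g.gene_id] = set(rng.choice(terms, size=k, replace=False))

    # junction-read columns in truth for convenience
    for sid in samples:
        truth[f"reads_{sid}"] = counts[sid]

    return SimResult(
        config=config,
        genome=genome,
        genes=genes,
        circs=circs,
        tables=tables,
        stats=stats,
        mites=mites,
        gene_abundance=gene_abundance,
        mirnas=mirnas,
        mrnas=mrnas,
        gene_terms=gene_terms,
        truth=truth,
        planted_mrna_targets=planted_mrna_targets,
    )


FIXTURE_NAMES = ("tiny", "paper_mix", "null_de", "de_benchmark")


def make_fixture(name: str) -> SimResult:
    """Deterministic bundled datasets used throughout the test suite.

    tiny: 2 chromosomes, 5 genes, 12 circRNAs -- fast smoke fixture.
    paper_mix: defaults (origin mix 79.5/4.9/15.6, canonical 11.7%) at a
        fixed seed.
    null_de: no differential circs in truth.
    de_benchmark: single tissue, 500 circs, 20% differential at 4-fold,
        negative-binomial dispersion 0.2, 2 replicates -- the caller
        benchmark condition.
    """
    if name == "tiny":
        cfg = SimConfig(
            seed=11,
            n_chromosomes=2,
            chromosome_length=80_000,
            n_scaffolds=1,
            scaffold_length=8_000,
            n_genes=5,
            n_circs=12,
            planted_flank_fraction=0.1,
            mite_fraction=0.1,
            flank_window=500,
            n_mirnas=4,
            n_planted_circ_sites=2,
            n_mrnas=6,
        )
    elif name == "paper_mix":
        cfg = SimConfig(seed=101)
    elif name == "null_de":
        cfg = SimConfig(
            seed=33,
            n_chromosomes=2,
            chromosome_length=400_000,
            n_genes=60,
            n_circs=200,
            de_fraction=0.0,
        )
    elif name == "de_benchmark":
        cfg = SimConfig(
            seed=77,
            tissues=("R",),
            tissue_specific_fraction=0.0,
            n_circs=500,
            n_genes=140,
            de_fraction=0.2,
            de_fold=4.0,
            nb_dispersion=0.2,
            n_replicates=2,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
    return simulate(cfg)
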