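"""Readers and writers for the pipeline's text formats.

BED/BEDPE files are written 0-based half-open and coordinate sorted; TSVs
carry a header row and may start with ``#``-prefixed comment lines (the
generator records its seed there).  Readers validate coordinates on load.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .anchors import Peak
from .chain import ChainAlignment, parse_chain, write_chain
from .concordance import ConservationTrack
from .disease import CNVRecord, PWM, RiskVariant
from .genes import GeneModels
from .intervals import GenomicInterval


# ---------------------------------------------------------------------------
# generic TSV
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path,
              comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path,
                      comment: str | None = None) -> None:
    df = pd.DataFrame(sorted(sizes.items()), columns=["chrom", "size"])
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              comment: str | None = None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        row = [iv.chrom, iv.start, iv.end]
        if names is not None:
            row.append(names[i])
        rows.append(row)
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            name = parts[3] if len(parts) > 3 else ""
            out.append((iv, name))
    return out


def write_bedpe(pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
                path: str | Path,
                extra: pd.DataFrame | None = None,
                comment: str | None = None) -> None:
    rows = []
    for i, (a, b) in enumerate(pairs):
        row = [a.chrom, a.start, a.end, b.chrom, b.start, b.end]
        if extra is not None:
            row.extend(extra.iloc[i].tolist())
        rows.append(row)
    rows.sort(key=lambda r: (r[0], r[1], r[3], r[4]))
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_bedpe(path: str | Path, n_extra: int = 0):
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            a = GenomicInterval(p[0], int(p[1]), int(p[2]))
            b = GenomicInterval(p[3], int(p[4]), int(p[5]))
            out.append((a, b, tuple(p[6:6 + n_extra])))
    return out


# ---------------------------------------------------------------------------
# peaks, conservation, variants, CNVs, PWMs
# ---------------------------------------------------------------------------

def write_peaks(peaks: Sequence[Peak], path: str | Path,
                comment: str | None = None) -> None:
    write_bed([p.interval for p in peaks], path,
              names=[p.mark for p in peaks], comment=comment)


def read_peaks(path: str | Path, tissue: str = "") -> list[Peak]:
    return [Peak(iv, mark, tissue) for iv, mark in read_bed(path)]


def write_bedgraph(track: ConservationTrack, path: str | Path,
                   comment: str | None = None) -> None:
    df = track.to_frame()
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, header=False,
                  float_format="%.4f")


def read_bedgraph(path: str | Path) -> ConservationTrack:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "score"])
    return ConservationTrack(
        (str(r.chrom), int(r.start), int(r.end), float(r.score))
        for r in df.itertuples(index=False))


def write_variants(variants: Sequence[RiskVariant], path: str | Path,
                   comment: str | None = None) -> None:
    df = pd.DataFrame({
        "chrom": [v.chrom for v in variants],
        "pos": [v.pos for v in variants],
        "rsid": [v.rsid for v in variants],
        "ref": [v.ref for v in variants],
        "alt": [v.alt for v in variants],
        "trait": [v.trait for v in variants],
        "ppa": [v.ppa for v in variants],
    }).sort_values(["chrom", "pos"]).reset_index(drop=True)
    write_tsv(df, path, comment=comment)


def read_variants(path: str | Path) -> list[RiskVariant]:
    df = read_tsv(path)
    return [RiskVariant(rsid=str(r.rsid), chrom=str(r.chrom), pos=int(r.pos),
                        ref=str(r.ref), alt=str(r.alt), trait=str(r.trait),
                        ppa=float(r.ppa))
            for r in df.itertuples(index=False)]


def write_cnvs(cnvs: Sequence[CNVRecord], path: str | Path,
               comment: str | None = None) -> None:
    df = pd.DataFrame({
        "chrom": [c.interval.chrom for c in cnvs],
        "start": [c.interval.start for c in cnvs],
        "end": [c.interval.end for c in cnvs],
        "type": [c.cnv_type for c in cnvs],
        "cohort": [c.cohort for c in cnvs],
        "phenotype": [c.phenotype for c in cnvs],
        "subject": [c.subject_id for c in cnvs],
        "pathogenicity_class": [c.pathogenicity_class for c in cnvs],
    })
    write_tsv(df, path, comment=comment)


def read_cnvs(path: str | Path) -> list[CNVRecord]:
    df = read_tsv(path)
    return [CNVRecord(interval=GenomicInterval(str(r.chrom), int(r.start),
                                               int(r.end)),
                      cnv_type=str(r.type), cohort=str(r.cohort),
                      phenotype=str(r.phenotype), subject_id=str(r.subject),
                      pathogenicity_class=str(r.pathogenicity_class))
            for r in df.itertuples(index=False)]


def write_pwms(pwms: Sequence[PWM], path: str | Path,
               comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.tf_name}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pwms(path: str | Path) -> list[PWM]:
    pwms = []
    motif_id = tf_name = None
    rows: list[tuple[float, ...]] = []

    def flush():
        nonlocal rows
        if motif_id is not None:
            norm = tuple(tuple(v / sum(r) for v in r) for r in rows)
            pwms.append(PWM(motif_id=motif_id, tf_name=tf_name, matrix=norm))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                motif_id = parts[0]
                tf_name = parts[1] if len(parts) > 1 else parts[0]
            else:
                rows.append(tuple(float(v) for v in line.split()))
    flush()
    return pwms


# ---------------------------------------------------------------------------
# genes, genome, WashU track
# ---------------------------------------------------------------------------

def write_genes(genes: GeneModels, path: str | Path,
                comment: str | None = None) -> None:
    write_tsv(genes.to_frame(), path, comment=comment)


def read_genes(path: str | Path) -> GeneModels:
    return GeneModels.from_frame(read_tsv(path))


def write_fasta(genome, path: str | Path, width: int = 80) -> None:
    """Write a SyntheticGenome (or mapping chrom -> sequence) as FASTA."""
    with open(path, "w") as fh:
        chroms = (sorted(genome.chrom_sizes) if hasattr(genome, "chrom_sizes")
                  else sorted(genome))
        for chrom in chroms:
            seq = (genome.fetch(chrom, 0, genome.chrom_sizes[chrom])
                   if hasattr(genome, "fetch") else genome[chrom])
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def fasta_fetcher(path: str | Path):
    """Return a ``fetch(chrom, start, end) -> str`` backed by an indexed FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))

    def fetch(chrom: str, start: int, end: int) -> str:
        return str(fa[chrom][max(0, start):end]).upper()

    return fetch


def write_washu_longrange(records, path: str | Path,
                          comment: str | None = None) -> None:
    """WashU longrange text: ``chrA  startA  endA  chrB:startB-endB,score``.

    Only records with both anchors remapped to the same chromosome are
    loops; the score is the PET count.
    """
    rows = []
    for r in records:
        if r.human_promoter is None or r.human_enhancer is None:
            continue
        a, b = r.human_promoter, r.human_enhancer
        rows.append((a.chrom, a.start, a.end,
                     f"{b.chrom}:{b.start}-{b.end},{r.pet_count}"))
    rows.sort()
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def read_washu_longrange(path: str | Path):
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, partner = line.split("\t")
            loc, score = partner.rsplit(",", 1)
            chrom2, span = loc.split(":")
            s2, e2 = span.split("-")
            out.append((GenomicInterval(chrom, int(start), int(end)),
                        GenomicInterval(chrom2, int(s2), int(e2)),
                        int(score)))
    return out


# ---------------------------------------------------------------------------
# chain convenience + config + checksums
# ---------------------------------------------------------------------------

def write_chain_file(chains: Sequence[ChainAlignment], path: str | Path,
                     comment: str | None = None) -> None:
    with open(path, "w") as fh:
        write_chain(chains, fh, header_comment=comment)


def read_chain_file(path: str | Path) -> list[ChainAlignment]:
    with open(path) as fh:
        return parse_chain(fh)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` text configuration."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_config(cfg: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in cfg:
            fh.write(f"{key} = {cfg[key]}\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
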