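#!/usr/bin/env python
"""Full-scale check: unmappable fraction of a real genome assembly.

Published mappability analyses of the GRCh38 primary assembly report that
regions unmappable for 30 bp reads cover about 12.4% of the human genome.
Reproducing that figure requires the assembly FASTA (~3 GB, user-provided;
alt/patch sequences must be excluded beforehand) and several CPU-hours, so
this is a standalone runner rather than part of the test suite. For a
per-chromosome smoke run on real data, pass a single-chromosome FASTA.

Usage:
    python scripts/grch38_unmappable.py --fasta GRCh38.primary.fa \
        --read-length 30 [--out-bed unmappable.bed]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from cistromeqc import io_formats as iof
from cistromeqc import mappability as mp


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fasta", type=Path, required=True)
    parser.add_argument("--read-length", type=int, default=30)
    parser.add_argument("--out-bed", type=Path)
    args = parser.parse_args()

    genome = iof.read_fasta(args.fasta)
    print(f"{len(genome)} sequences, {sum(map(len, genome.values())):,} bp")
    mul = mp.mul_for_genome(genome)
    fraction = mp.unmappable_fraction(mul, args.read_length)
    print(
        f"unmappable fraction at k={args.read_length}: {fraction:.4f} "
        f"({fraction * 100:.1f}%)"
    )
    if args.out_bed:
        iof.write_bed(mp.unmappable_regions(mul, args.read_length), args.out_bed)
        print(f"regions written to {args.out_bed}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
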