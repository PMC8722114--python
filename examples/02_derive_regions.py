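"""From per-run region files to callable regions.

Each alignment run contributes a BED of covered intervals ("region file").
Their union is the sample's mappable regions; ranking mappable bases by how
many region files cover them and keeping the top 99% (base-weighted) gives
the consensus mappable regions; subtracting difficult-region masks yields
the callable regions.
"""

from hrrforge.regions import (
    build_coverage_stack,
    consensus_threshold,
    select_consensus,
    subtract_difficult,
    union_regions,
)
from hrrforge.simulate import SimulationConfig, simulate_region_files

config = SimulationConfig(
    genome=(("chr1", 500_000),),
    labs=("lab1", "lab2", "lab3"),
    replicates=("r1", "r2", "r3"),
    aligners=("alnA", "alnB"),
    seed=7,
)
region_files, masks = simulate_region_files(config)

sample = config.samples[0]
files = [rs for (s, *_), rs in region_files.items() if s == sample]
print(f"{sample}: {len(files)} region files (lab x replicate x aligner runs)")

mappable = union_regions(files)
stack = build_coverage_stack(files)
k = consensus_threshold(stack, fraction=0.99)
consensus = select_consensus(stack, k)
callable_rs = subtract_difficult(consensus, masks)

print(f"mappable (union)  : {mappable.total_bases:>7} bp")
print(f"consensus (>= {k:>2}) : {consensus.total_bases:>7} bp "
      f"({consensus.total_bases / mappable.total_bases:.1%} of mappable)")
print(f"callable (masked) : {callable_rs.total_bases:>7} bp")
# k is the most stringent coverage-count threshold that still retains 99%
# of mappable bases; with 18 region files and modest dropout it sits close
# to the number of files.
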