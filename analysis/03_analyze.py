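"""Compare reconstructed fossils and reference groups.

Symmetrizes every configuration, removes ribs 11-12, superimposes by GPA,
then runs centroid-size permutation tests (10,000 permutations), builds
the UPGMA dendrogram of group distances, and ordinates shape space by PCA
with PC-score permutation tests.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import make_config  # noqa: E402

from thoraxgm.pipeline import cmd_analyze  # noqa: E402


def main() -> None:
    config = make_config()
    out = cmd_analyze(config)
    print("centroid size by group:")
    print(out["summary"].to_string(index=False))
    print("\npairwise permutation tests (centroid size):")
    print(out["size_pvalues"].to_string(index=False))
    vf = out["variance_fractions"]
    print(f"\nshape-space PCA: PC1 {100 * vf[0]:.1f}% of variance, "
          f"PC2 {100 * vf[1]:.1f}%")
    print(f"UPGMA dendrogram: {out['newick']}")
    print(f"tables under {config.output_dir}")


if __name__ == "__main__":
    main()
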