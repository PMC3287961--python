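"""Score a protein pair against a composition-preserved shuffle null.

The observed global (Needleman-Wunsch) score is compared with the mean and
standard deviation of scores against 50 residue-shuffles of the second
sequence; Z = (observed - mean)/SD and confidence = Phi(Z).  Pairs above
99.9999% confidence are accepted as orthologs during clustering; 99.0% is
the threshold for calling an outgroup sequence a homolog.
"""

import numpy as np

from panhog import ScoringScheme, global_align, randomized_significance
from panhog.synthetic_data import mutate_protein, random_protein

rng = np.random.default_rng(0)
scheme = ScoringScheme()  # BLOSUM62, gap open 11 / extend 1

ancestor = random_protein(150, rng)
diverged = mutate_protein(ancestor, 0.45, rng)   # 45% identity homolog
unrelated = random_protein(150, rng)

for name, other in (("45%-identity homolog", diverged),
                    ("unrelated protein", unrelated)):
    aln = global_align(ancestor, other, scheme)
    sig = randomized_significance(ancestor, other, scheme, rng=rng)
    print(f"{name}: score {aln.score:.0f}, identity {aln.percent_identity:.1f}%, "
          f"null {sig.null_mean:.1f} +/- {sig.null_sd:.1f}, "
          f"Z {sig.z:.2f}, confidence {sig.confidence:.6f}")
# the homolog stands far outside the null (Z >> 4.75); the unrelated pair
# behaves like one more draw from it and does not clear either threshold
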