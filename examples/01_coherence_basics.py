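"""Link coherence and subnetwork boundaries on a toy signed network.

Builds a five-gene network with inducing and inhibiting links, applies the
sign-product coherence rule to a set of differential-expression estimates,
and prints which links survive and what the boundary of the result looks
like.
"""

from cone import (
    SignedLink,
    SignedNetwork,
    boundary,
    coherence_filter,
    is_coherent,
)

# A -> B -> C is an inducing cascade; C -| D is inhibiting; D - E inducing.
network = SignedNetwork(
    [
        SignedLink("A", "B", "non_inhibiting"),
        SignedLink("B", "C", "non_inhibiting"),
        SignedLink("C", "D", "inhibiting"),
        SignedLink("D", "E", "non_inhibiting"),
    ]
)

# Estimated log-expression changes: the cascade is up, D is up too (which
# contradicts the inhibition from C), E is down.
deltas = {"A": 1.2, "B": 0.8, "C": 1.5, "D": 0.9, "E": -0.4}

print("link coherence under the sign-product rule:")
for link in network.links:
    ok = is_coherent(deltas[link.source], deltas[link.target], link.weight)
    print(f"  {link.source}-{link.target} ({link.relationship.value:>15}): "
          f"{'coherent' if ok else 'incoherent'}")

sub = coherence_filter(network, deltas)
print(f"\ncoherent subnetwork: genes={sorted(sub.genes)}, "
      f"links={sorted(sub.link_keys)}")

bnd = boundary(network, sub, deltas)
print(f"boundary: incoherent internal={sorted(bnd.incoherent_internal)}, "
      f"crossing={sorted(bnd.crossing)}")
# The A-B-C cascade is kept; C-|D fails (both up across an inhibition) and
# D-E fails (opposite signs across an induction), so D and E drop out.  The
# boundary of the kept core is the single crossing link C-D; there are no
# incoherent links inside the core itself.
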