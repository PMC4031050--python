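"""Shared fixtures: one synthetic kinked-bundle target/template pair.

The pair is built once per session: a 3-helix bundle whose second TMH
carries a 30-degree proline kink, and a homolog-like template in which that
kink is straightened, the proline replaced, loops shortened, the sequence
mutated to ~35% identity, and coordinates perturbed.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from tmrebuild import (BundleSpec, Kink, make_kinked_bundle,
                       make_template_from_target, bundle_layout,
                       make_alignment, derive_constraints,
                       build_fragment_library, thread_template)

KINK = Kink(helix_id=2, bend_position=7, kink_angle=30.0, swing=0.0)
TARGET_SPEC = BundleSpec(kinks=(KINK,), seed=1)
TEMPLATE_SPEC = BundleSpec(kinks=(KINK,), seed=1, straighten=(2,),
                           seq_identity_target=0.35, perturbation=0.2,
                           loop_delete=2)


@pytest.fixture(scope="session")
def frag_lib():
    return build_fragment_library("ideal")


@pytest.fixture(scope="session")
def bundle_pair():
    target, annotations = make_kinked_bundle(TARGET_SPEC)
    fx = make_template_from_target(target, TEMPLATE_SPEC)
    layout = bundle_layout(TARGET_SPEC)
    return SimpleNamespace(
        target=target, annotations=annotations, fx=fx, layout=layout,
        kink=layout.kink_specs[2],
        tm_residues=[r for lo, hi in layout.helices
                     for r in range(lo, hi + 1)],
    )


@pytest.fixture(scope="session")
def target_constraints(bundle_pair):
    """Constraints from the target's own contacts (recovery experiments)."""
    bp = bundle_pair
    self_aln = make_alignment(bp.target.sequence, bp.target.sequence)
    return derive_constraints(
        self_aln, bp.target,
        rebuilt_regions=[bp.kink.bend_range] + bp.layout.loops,
        cutoff=10.0)


@pytest.fixture(scope="session")
def threaded_start(bundle_pair):
    start, missing = thread_template(bundle_pair.fx.alignment,
                                     bundle_pair.fx.structure)
    return SimpleNamespace(structure=start, missing=missing)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
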