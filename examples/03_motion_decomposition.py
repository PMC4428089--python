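"""Decompose lung expansion into diaphragm vs chest-wall contributions.

The diaphragm lengthens the lung cranial-caudally; the thoracic muscles
widen it anterior-posteriorly and left-right.  Comparing per-axis length
ratios therefore separates the two muscle groups.  This script contrasts
a healthy-type phantom (large diaphragmatic displacement) with a
weak-diaphragm phantom (motion mostly from the chest wall).
"""

from lungmorph import PhantomSpec, decompose, make_breath_pair, percent_increase

subjects = {
    "healthy-type": PhantomSpec(diaphragm_displacement=80.0,
                                ap_expansion=1.35, lr_expansion=1.25, seed=1),
    "weak-diaphragm": PhantomSpec(diaphragm_displacement=10.0,
                                  ap_expansion=1.40, lr_expansion=1.35, seed=2),
}

for name, spec in subjects.items():
    pair, _ = make_breath_pair(spec, subject_id=name)
    res = decompose(pair)["combined"]
    print(f"\n{name}:")
    print(f"  diaphragm (CC):   ratio {res.diaphragm_component:.2f} "
          f"(+{percent_increase(res.diaphragm_component):.0f}% length)")
    for axis, ratio in res.chestwall_components.items():
        print(f"  chest wall ({axis}): ratio {ratio:.2f} "
              f"(+{percent_increase(ratio):.0f}% length)")
    print(f"  classified as {res.dominance}")
# A ratio of 1.2 means the lung is 20% longer on that axis at maximum
# inspiration than at maximum expiration.
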