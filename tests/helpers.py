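"""Small construction helpers shared across test modules."""

from cortstress import CortSample, Dataset, Sex, Treatment


def toy_dataset(cort_values, times=None, treatments=None, sexes=None,
                provenance="toy"):
    """Build a Dataset directly from parallel value lists."""
    n = len(cort_values)
    times = times if times is not None else [float(i) for i in range(n)]
    treatments = treatments if treatments is not None else [Treatment.TRAPPED] * n
    sexes = sexes if sexes is not None else [Sex.UNKNOWN] * n
    samples = [
        CortSample(
            bird_id=f"t{i:03d}",
            treatment=treatments[i],
            sex=sexes[i],
            time_min=float(times[i]),
            cort=float(cort_values[i]),
        )
        for i in range(n)
    ]
    return Dataset(samples=tuple(samples), provenance=provenance)
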