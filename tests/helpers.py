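from tumorlr.str_io import LocusObservation, Peak, STRProfile


def make_evidence(alleles_by_locus, sample="E"):
    prof = STRProfile(sample_id=sample, kind="evidence")
    for locus, alleles in alleles_by_locus.items():
        prof.loci[locus] = LocusObservation(locus=locus, peaks=[
            Peak(a, 1000.0, 100.0 + 4 * i) for i, a in enumerate(alleles)])
    return prof


def make_reference(alleles_by_locus, sample="R"):
    prof = STRProfile(sample_id=sample, kind="reference")
    for locus, alleles in alleles_by_locus.items():
        prof.loci[locus] = LocusObservation(locus=locus, peaks=[
            Peak(a, None, None) for a in alleles])
    return prof
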