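# Drosophila melanogaster V-ATPase subunit and accessory genes
# (constitutive V1 and V0 subunits, isoforms, and accessory proteins).
# Lines starting with '#' are comments.
Vha100-1
Vha100-2
Vha100-3
Vha100-4
Vha100-5
Vha16-1
Vha16-2
Vha16-3
Vha16-5
VhaPPA1-1
VhaPPA1-2
VhaAC39-1
VhaAC39-2
VhaAC45
CG31030
VhaM9.7-a
VhaM9.7-b
VhaM9.7-c
VhaM9.7-d
VhaM8.9
Vha13
Vha14-1
Vha14-2
Vha26
Vha36-1
Vha36-2
Vha36-3
Vha44
Vha55
Vha68-1
Vha68-2
Vha68-3
VhaSFD
ATP6AP2
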