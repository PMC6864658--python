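site,community,Darwin,Alder,Del Paso,Wyman,Coroval,Socorro,24th Ave,Henrietta,Hermosa,Tristan,ARB T St,T St Tier 3,13th Ave,64th St,79th St
Darwin,Arden,0,0.07,0.07,0.08,0.16,0.09,0.11,0.11,0.2,0.14,0.18,0.2,0.11,0.08,0.12
Alder,Del Paso,0.16,0,0.06,0.09,0.19,0.12,0.15,0.15,0.21,0.15,0.21,0.22,0.13,0.09,0.13
Del Paso,Del Paso,0.14,0.14,0,0.08,0.18,0.12,0.14,0.14,0.2,0.13,0.2,0.21,0.11,0.11,0.13
Wyman,Del Paso,0.18,0.15,0.17,0,0.18,0.14,0.14,0.14,0.2,0.14,0.2,0.2,0.13,0.12,0.13
Coroval,South Natomas,0.23,0.28,0.25,0.3,0,0.11,0.1,0.13,0.16,0.15,0.11,0.12,0.16,0.14,0.14
Socorro,South Natomas,0.17,0.23,0.21,0.25,0.16,0,0.09,0.11,0.18,0.15,0.15,0.17,0.12,0.1,0.13
24th Ave,South Sacramento,0.18,0.24,0.21,0.26,0.18,0.17,0,0.08,0.14,0.12,0.09,0.13,0.12,0.09,0.09
Henrietta,South Sacramento,0.21,0.26,0.23,0.27,0.2,0.19,0.14,0,0.16,0.13,0.13,0.15,0.13,0.11,0.11
Hermosa,South Sacramento,0.24,0.28,0.25,0.29,0.22,0.23,0.17,0.2,0,0.12,0.15,0.13,0.18,0.18,0.15
Tristan,South Sacramento,0.23,0.27,0.22,0.27,0.24,0.24,0.17,0.2,0.2,0,0.16,0.13,0.11,0.14,0.11
ARB T St,T St,0.23,0.27,0.25,0.29,0.17,0.19,0.14,0.19,0.19,0.22,0,0.12,0.18,0.14,0.14
T St Tier 3,T St,0.28,0.33,0.28,0.33,0.22,0.27,0.2,0.23,0.23,0.18,0.21,0,0.17,0.19,0.13
13th Ave,Tahoe Park,0.21,0.23,0.22,0.26,0.25,0.22,0.2,0.23,0.25,0.23,0.25,0.28,0,0.11,0.11
64th St,Tahoe Park,0.15,0.18,0.19,0.22,0.23,0.17,0.16,0.19,0.22,0.22,0.2,0.29,0.19,0,0.09
79th St,Tahoe Park,0.18,0.21,0.19,0.22,0.23,0.21,0.17,0.21,0.2,0.17,0.21,0.21,0.16,0.14,0
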