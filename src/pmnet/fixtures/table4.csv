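site,community,Darwin,Alder,Del Paso,Wyman,Coroval,Socorro,24th Ave,Henrietta,Hermosa,Tristan,ARB T St,T St Tier 3,13th Ave,64th St,79th St
Darwin,Arden,1,0.99,0.89,0.98,0.98,0.92,0.9,0.83,0.84,0.9,0.85,0.81,0.94,0.94,0.91
Alder,Del Paso,0.96,1,0.88,0.98,0.98,0.92,0.9,0.83,0.85,0.9,0.85,0.81,0.95,0.95,0.92
Del Paso,Del Paso,0.73,0.72,1,0.87,0.93,0.97,0.97,0.91,0.94,0.93,0.95,0.96,0.93,0.94,0.91
Wyman,Del Paso,0.94,0.94,0.71,1,0.97,0.91,0.89,0.83,0.83,0.9,0.85,0.81,0.93,0.93,0.9
Coroval,South Natomas,0.93,0.92,0.82,0.9,1,0.97,0.94,0.89,0.88,0.92,0.88,0.86,0.96,0.96,0.92
Socorro,South Natomas,0.81,0.81,0.92,0.79,0.89,1,0.96,0.91,0.92,0.93,0.91,0.91,0.95,0.95,0.89
24th Ave,South Sacramento,0.79,0.8,0.89,0.77,0.86,0.89,1,0.94,0.97,0.98,0.97,0.96,0.97,0.98,0.94
Henrietta,South Sacramento,0.74,0.74,0.84,0.73,0.81,0.84,0.89,1,0.9,0.9,0.91,0.92,0.9,0.92,0.87
Hermosa,South Sacramento,0.71,0.73,0.83,0.71,0.78,0.81,0.91,0.81,1,0.96,0.96,0.96,0.93,0.94,0.92
Tristan,South Sacramento,0.78,0.8,0.79,0.77,0.81,0.81,0.91,0.81,0.86,1,0.96,0.95,0.97,0.97,0.95
ARB T St,T St,0.72,0.72,0.9,0.7,0.8,0.85,0.94,0.85,0.9,0.87,1,0.98,0.94,0.95,0.93
T St Tier 3,T St,0.68,0.69,0.88,0.67,0.77,0.83,0.9,0.84,0.87,0.84,0.95,1,0.91,0.92,0.92
13th Ave,Tahoe Park,0.87,0.88,0.82,0.84,0.9,0.87,0.9,0.83,0.83,0.89,0.84,0.79,1,0.99,0.96
64th St,Tahoe Park,0.87,0.88,0.82,0.85,0.9,0.86,0.92,0.84,0.86,0.9,0.86,0.83,0.95,1,0.97
79th St,Tahoe Park,0.82,0.84,0.76,0.79,0.84,0.77,0.86,0.75,0.83,0.87,0.82,0.8,0.91,0.94,1
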