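site,community,Darwin,Alder,Del Paso,Wyman,Coroval,Socorro,24th Ave,Henrietta,Hermosa,Tristan,ARB T St,T St Tier 3,13th Ave,64th St,79th St
Darwin,Arden,0.0,,,,,,,,,,,,,,
Alder,Del Paso,4.8,0.0,,,,,,,,,,,,,
Del Paso,Del Paso,4.4,0.9,0.0,,,,,,,,,,,,
Wyman,Del Paso,5.3,1.9,1.2,0.0,,,,,,,,,,,
Coroval,South Natomas,8.4,13.3,12.8,13.5,0.0,,,,,,,,,,
Socorro,South Natomas,6.1,10.9,10.5,11.1,2.4,0.0,,,,,,,,,
24th Ave,South Sacramento,8.1,11.6,11.7,12.8,7.5,6.9,0.0,,,,,,,,
Henrietta,South Sacramento,15.7,17.9,18.3,19.5,15.2,15.2,8.3,0.0,,,,,,,
Hermosa,South Sacramento,14.3,15.7,16.2,17.4,15.6,15.1,8.2,3.3,0.0,,,,,,
Tristan,South Sacramento,15.0,15.8,16.4,17.6,17.0,16.3,9.5,4.7,1.7,0.0,,,,,
ARB T St,T St,8.2,12.2,12.1,13.2,6.1,5.9,1.5,9.3,9.5,10.9,0.0,,,,
T St Tier 3,T St,8.9,13.1,13.0,14.0,5.6,5.8,2.5,9.7,10.2,11.7,1.1,0.0,,,
13th Ave,Tahoe Park,8.2,9.8,10.2,11.5,11.1,9.9,4.3,8.0,6.2,6.9,5.7,6.8,0.0,,
64th St,Tahoe Park,9.1,10.2,10.7,12.0,12.5,11.2,5.5,7.8,5.5,5.9,7.0,8.1,1.3,0.0,
79th St,Tahoe Park,8.8,9.2,9.8,11.0,13.2,11.7,6.7,9.1,6.6,6.6,8.1,9.2,2.4,1.5,0.0
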