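country,iso3,bcuid
Australia,AUS,1
French Polynesia,PYF,2
French Polynesia,PYF,3
Australia,AUS,4
Indonesia,IDN,5
Australia,AUS,6
Australia,AUS,7
French Polynesia,PYF,8
Indonesia,IDN,9
Australia,AUS,10
Indonesia,IDN,11
Australia,AUS,12
Indonesia,IDN,13
Malaysia,MYS,13
Singapore,SGP,13
Kenya,KEN,14
Tanzania,TZA,14
Eritrea,ERI,15
Saudi Arabia,SAU,15
Yemen,YEM,15
Philippines,PHL,16
Indonesia,IDN,17
Malaysia,MYS,18
Philippines,PHL,18
Indonesia,IDN,19
Philippines,PHL,20
Djibouti,DJI,21
Eritrea,ERI,21
Somalia,SOM,21
Indonesia,IDN,23
Tanzania,TZA,24
Tanzania,TZA,25
Indonesia,IDN,27
Indonesia,IDN,32
French Polynesia,PYF,33
Philippines,PHL,34
Indonesia,IDN,35
Timor-Leste,TLS,35
Egypt,EGY,36
Sudan,SDN,36
Indonesia,IDN,38
Kenya,KEN,39
Somalia,SOM,39
Indonesia,IDN,40
Solomon Islands,SLB,42
Indonesia,IDN,43
Bahamas,BHS,44
India,IND,45
Saudi Arabia,SAU,47
India,IND,49
Sri Lanka,LKA,49
Cuba,CUB,50
Fiji,FJI,51
Brazil,BRA,52
Papua New Guinea,PNG,53
Cuba,CUB,54
Dominican Republic,DOM,54
Haiti,HTI,54
Bangladesh,BGD,56
Myanmar,MMR,56
Bahamas,BHS,57
Bahamas,BHS,58
Cuba,CUB,58
Cuba,CUB,59
Indonesia,IDN,60
Fiji,FJI,61
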