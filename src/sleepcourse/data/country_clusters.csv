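country,maddison_cluster,cultural_cluster,weird
South Africa,African,African,False
Egypt,African,African,False
Czech Republic,East Europe,East Europe,False
Hungary,East Europe,East Europe,False
Poland,East Europe,East Europe,False
Romania,East Europe,East Europe,False
Russia,East Europe,East Europe,False
Slovakia,East Europe,East Europe,False
Ukraine,East Europe,East Europe,False
Albania,East Europe,East Europe,False
Serbia,East Europe,East Europe,False
Croatia,East Europe,East Europe,False
Macedonia,East Europe,East Europe,False
Cyprus,East Europe,East Europe,False
Germany,Western Europe,Germanic,True
Austria,Western Europe,Germanic,True
Switzerland,Western Europe,Germanic,True
England,Western Europe,Anglo,True
Ireland,Western Europe,Anglo,True
Sweden,Western Europe,Nordic,True
Norway,Western Europe,Nordic,True
Finland,Western Europe,Nordic,True
Denmark,Western Europe,Nordic,True
Netherlands,Western Europe,Nordic,True
France,Western Europe,Latin Europe,True
Belgium,Western Europe,Latin Europe,True
Italy,Western Europe,Latin Europe,True
Portugal,Western Europe,Latin Europe,True
Spain,Western Europe,Latin Europe,True
Greece,Western Europe,Near East,True
United Arab Emirates,Western Asia,Arabic,False
Saudi Arabia,Western Asia,Arabic,False
Turkey,Western Asia,Near East,False
Israel,Western Asia,Latin Europe,False
Lebanon,Western Asia,Near East,False
Iran,Western Asia,Near East,False
United States,Western Offshoot,Anglo,True
Canada,Western Offshoot,Anglo,True
Australia,Western Offshoot,Anglo,True
New Zealand,Western Offshoot,Anglo,True
Argentina,Latin America,Latin America,False
Peru,Latin America,Latin America,False
Chile,Latin America,Latin America,False
Bolivia,Latin America,Latin America,False
Colombia,Latin America,Latin America,False
Puerto Rico,Latin America,Latin America,False
Ecuador,Latin America,Latin America,False
Costa Rica,Latin America,Latin America,False
Venezuela,Latin America,Latin America,False
Uruguay,Latin America,Latin America,False
Brasil,Latin America,Latin America,False
Mexico,Latin America,Latin America,False
India,East Asia,Far East,False
Indonesia,East Asia,Far East,False
Malaysia,East Asia,Far East,False
Philippines,East Asia,Far East,False
Thailand,East Asia,Far East,False
Vietnam,East Asia,Far East,False
China,East Asia,Confucian Asia,False
Singapore,East Asia,Confucian Asia,False
Hong Kong,East Asia,Confucian Asia,False
Taiwan,East Asia,Confucian Asia,False
Japan,East Asia,Confucian Asia,False
South Korea,East Asia,Confucian Asia,False
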